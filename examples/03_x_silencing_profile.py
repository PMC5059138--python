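"""Female/male X dosage across development: imprinted X inactivation kinetics.

WT females start near two-fold male X expression (two active X chromosomes)
and compensate to male levels by E4.5 as the paternal X is silenced; RlimKO
females track WT through E3.0 and then fail to complete silencing.
"""

from xdosage import SimulationConfig, fm_profile, preprocess, simulate_experiment

config = SimulationConfig(seed=11, n_embryos=12)
counts, annotation, samples = simulate_experiment(config)
norm = preprocess(counts, annotation, samples)

for genotype in ("WT", "RlimKO"):
    profile = fm_profile(norm.fpkm, norm.samples, annotation,
                         female_genotype=genotype, retained=norm.retained,
                         compare_genotype="WT" if genotype != "WT" else None)
    print(f"\nF/M ratio of X-linked FPKM (minus Xist), {genotype} females:")
    print(profile[["value", "sem", "n_genes"]].round(3))
# The WT column falls from ~1.9 to ~1.0; RlimKO plateaus around 1.5-1.6 after
# E3.0 — silencing that starts but cannot be maintained without Rlim.
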