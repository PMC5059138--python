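"""Simulate a single-embryo RNA-seq experiment and inspect its design.

Generates counts for male and female WT and RlimKO embryos across the seven
pre/peri-implantation stages, with a mouse-like karyotype and
negative-binomial noise, then prints the design summary and a few marker
genes.  The same seed always reproduces the same matrix byte for byte.
"""

from xdosage import SimulationConfig, simulate_experiment

config = SimulationConfig(seed=42, n_embryos=4)
counts, annotation, samples = simulate_experiment(config)

print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} embryos")
print("\nembryos per (stage, genotype, sex):")
print(samples.groupby(["stage", "genotype", "true_sex"], sort=False).size()
      .unstack("true_sex").head(8))

print("\ngenes per chromosome (first few):")
print(annotation["chromosome"].value_counts().sort_index().head(6).to_dict())

females = samples.index[samples["true_sex"] == "female"]
males = samples.index[samples["true_sex"] == "male"]
xist_f = counts.loc["Xist", females].mean()
xist_m = counts.loc["Xist", males].mean()
print(f"\nmean Xist counts: females {xist_f:.0f}, males {xist_m:.1f}")
print("Y-marker counts are zero in females:",
      counts.loc[annotation["role"] == "y_marker", females].to_numpy().sum() == 0)
# Xist is female-specific and Y markers male-specific: the two markers that
# drive sex assignment downstream.
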