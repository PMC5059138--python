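"""Allele-resolved Xp/Xm expression in hybrid females at E3.5.

In a B6 x CAST cross, strain SNPs assign a fraction of reads to the
maternal (B6) or paternal (CAST) allele.  Imprinted X inactivation silences
the paternal X, so the pooled paternal/maternal ratio of X-linked reads in
females directly measures the silencing fraction; autosomes stay at ~1.
"""

from xdosage import (
    allelic_ratio,
    assign_sex,
    hybrid_config,
    qc_filter,
    simulate_allelic,
    validate_snp_informativeness,
)

config = hybrid_config(seed=19, n_embryos=10, stages=("E3.5",))
allelic, counts, annotation, samples = simulate_allelic(config)

samples = samples.copy()
samples["sex"] = assign_sex(counts, annotation)
samples = qc_filter(counts, samples)

report = validate_snp_informativeness(allelic, annotation, samples)
flagged = report.index[report["flagged"]]
print(f"genes with paternal X signal in males (mis-assigned SNPs): {len(flagged)}")

result = allelic_ratio(allelic, annotation, samples, exclude_genes=flagged)
print(f"X-linked paternal/maternal ratio in females: {result.ratio:.3f}")
print(f"autosomal control ratio: {result.autosomal_ratio:.3f}")
print(f"genes used: {result.n_genes}, females used: {result.n_samples}")
# At E3.5 about half the paternal X is silenced, so the X ratio sits near
# 0.5 while the autosomal control stays at 1.0.
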