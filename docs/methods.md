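# Methods

## The biological model

The package analyses chromosome-level dosage in early mouse embryos, where
two processes overlap:

* **Imprinted X inactivation (iXCI).** Female embryos progressively silence
  the paternally inherited X (Xp). We summarize the silenced fraction at
  stage *s* as σ(s) ∈ [0, 1]; female X output is then proportional to
  1 + (1 − σ) active-X equivalents against 1 in males, so the expected
  female/male (F/M) expression ratio of X-linked genes is 2 − σ.
* **Active-X upregulation.** Both sexes increase expression from each
  active X relative to autosomes, modeled as a per-stage multiplier u(s) on
  active alleles.

Everything in the pipeline is a chromosome-level aggregate; no attempt is
made to model locus-level behavior (escape genes, read pileups within the
*Xist*/*Tsix* locus) beyond exporting per-gene tracks.

## The synthetic-data generator

`simulate_experiment` draws a mouse-like annotation (19 autosomes with
400–1200 genes each by default, 700 X-linked genes, the 7 Y marker genes,
13 mitochondrial genes) and per-gene expression levels θ_g (per-kilobase
rates, log-normal with σ = 0.8) and exonic lengths (log-normal, median
2 kb; *Xist* fixed at its real 17,918 bp). Expected counts for embryo *e*
are the gene's relative rate normalized to a log-normal library size
(median 5×10⁵ reads, σ = 0.35); counts are gamma-Poisson with variance
μ + φμ² (φ = 0.3 by default, the standard RNA-seq negative-binomial
parameterization).

Gene rates carry the dosage structure:

* autosomal gene: θ_g · len_g (bi-allelic total);
* X-linked gene, male: θ_g · len_g · b · u(s);
* X-linked gene, female: θ_g · len_g · b · u(s) · (2 − σ_eff(geno, s)),

with `baseline_x_factor` b = 0.49 (one active X expresses about half the
autosomal per-gene mean at the 4-cell stage) and u(s) linear from 1.0 at
the 4-cell stage to 1.58 at E4.5. Trophoblast, when enabled, is generated
E4.5-like with complete Xp silencing.

**Calibration is exact, not only in expectation.** The X-linked θ draws are
rescaled so the realized mean over ordinary X genes equals the mean over
ordinary autosomal genes before b is applied. A finite gene panel would
otherwise leave a few-percent sampling offset in every X/A statistic; the
rescaling makes the configured dosage the dataset's ground truth, which is
what parameter-recovery testing needs.

**Silencing trajectories.** Defaults per genotype across the 7 stages:
WT (0.00, 0.10, 0.25, 0.40, 0.50, 0.75, 0.97); RlimKO tracks WT through
E3.0 and then plateaus at 0.40 (initiation without maintenance); XistKO is
constant at 0.10. A small *Xist*-independent repression of the Xp (default
0.10) applies to every female genotype from the 4-cell stage; it combines
with the genotype trajectory as a **floor**, σ_eff = max(0.10, σ_traj), so
it is never double-counted against the XistKO trajectory that represents
the same phenomenon. Early female F/M therefore sits at ~1.9 rather than
exactly 2.

**Marker genes.** Female *Xist* follows a per-stage cpm profile peaking at
E3.5 (decaying after E3.0 in RlimKO, near zero in XistKO); males express
~0.5 cpm of *Xist*. *Tsix* is near-silent. Y markers are expressed at
~40 cpm each in males and exactly zero in females. *Rlim* is an ordinary
X-linked gene whose transcript drops to 2% in RlimKO embryos. A handful of
autosomal genes carry a residual-rRNA role and are dropped before analysis.

**Allelic mode.** `simulate_allelic` reuses the identical count matrix
(same seed, independent random stream for the split) and assigns
`informative_fraction` (default 0.35) of each gene's reads to an allele:
autosomes binomial 50:50, female X genes with paternal share
(1 − σ_eff)/(2 − σ_eff), male X fully maternal, Y paternal, mitochondria
maternal, *Xist* 95% paternal (it is transcribed from the inactive Xp).

**What the generator does not emulate.** Read mis-mapping background (so
female Y-marker counts are exactly zero and the Y split is cleaner than on
real data), silent/unexpressed genes (the panel represents the
post-filtering expressed-gene universe, so the low-expression filter
removes almost nothing), isoforms, cell-type mixtures within an embryo,
batch effects, and reference bias in allele assignment. Passing tests
therefore demonstrate correctness of the estimators under the stated noise
model, not robustness to artifacts absent from it.

## Preprocessing choices

* **Sex assignment** uses cpm on total (all-gene) library sizes, since it
  precedes filtering and normalization; calls are invariant to uniform
  library scaling. The Y threshold is an exact 1-D 2-means split of
  log₂(1+cpm) with a ±0.5 log₂ ambiguity margin around the gap midpoint.
  Because *Xist* rises ~50-fold across stages, a global 2-means on it can
  land inside the early-female range; the *Xist* threshold is instead
  derived from the Y-informed populations (just below the 5% quantile of
  the Y-low group, never below the Y-high median + margin). If the two
  populations are separated by less than 2 log₂ units, *Xist* is declared
  uninformative: males are still called from Y markers, females are not —
  the `xist_blind` mode exists for exactly that situation.
* **QC** removes embryos with strictly fewer than 280,000 total reads or no
  sex call, as a single combined flag.
* **Low-expression filter**: per stage, keep genes with cpm ≥ 1 (total-count
  libraries, i.e. before the library-size reset) in at least *n* samples,
  *n* = size of the smallest (sex × genotype) group at that stage. The
  grouping by sex × genotype (rather than mating) is a design choice; the
  filter is idempotent and its retained set only shrinks as *n* grows.
* **Effective library size** = summed retained autosomal counts; X, Y and
  MT are excluded (mitochondrial copy number would otherwise leak into the
  denominator).
* **TMM** is implemented in the package itself (it is part of the method
  under study, not an external step): within each stage, the reference is
  the sample whose 75th-percentile cpm is closest to the stage mean of 75th
  percentiles; M and A values are computed over genes positive in both
  sample and reference; 30% of each M tail and 5% of each A tail are
  trimmed by rank (average ranks on ties); the factor is 2 to the
  inverse-variance-weighted mean of the surviving M values (delta-method
  binomial variances); factors are rescaled to geometric mean 1 within the
  stage. TMM is computed on the retained **autosomal** genes, consistent
  with the autosomal anchoring of the library size — using all genes would
  let sex-differential X expression leak into the factors. Stages with a
  single sample get factor 1 with a warning.
* **cpm/FPKM**: cpm = counts·10⁶ / (effective library size × TMM factor);
  FPKM = cpm·10³ / exonic length. TMM factors enter the FPKM denominator,
  so there is a single consistent normalized unit throughout (the
  alternative — factors only in differential tests — was considered and
  rejected for consistency; all dosage statistics are ratios within or
  between samples of the same stage, so the choice is second-order).
* **Subsampling** draws exactly `depth` reads per library without
  replacement (multivariate hypergeometric over genes), leaving libraries
  already at or below the target unchanged with a warning.

## Dosage statistics

F/M profiles average per-gene ratios (female mean FPKM over pooled-male
mean FPKM) within a stage — mean-of-ratios, not ratio-of-means — with SEM
taken across genes. Genes whose male mean falls below 0.1 FPKM are excluded
to avoid ratio blow-up; the floor is configurable. *Xist* is excluded from
every X-linked aggregate (it is expression of the silencing machinery, not
of the silenced chromosome), and Y genes never enter F/M or X/A statistics.
"Pooled males" means all QC-passing males regardless of genotype, since
males are unaffected by iXCI genotype. Two-sample tests are two-sided
Welch; the paired test pairs by stage. No multiple-testing correction is
applied by default. All aggregates are invariant under a common positive
rescaling of every sample's FPKM.

`estimate_silencing` inverts the F/M expectation (σ̂ = 2 − F/M) after a
first-order ratio-bias correction: the raw mean-of-ratios overshoots by
E[f̄/m̄] ≈ (f/m)(1 + Var(m̄)/m̄²), a few percent at 20 embryos per group with
NB dispersion 0.3, which matters when recovering σ to ±0.05. The correction
divides each per-gene ratio by (1 + s²_m/(n·m̄²)) with sample estimates.
`fm_profile` itself reports the uncorrected mean-of-ratios, matching the
published definition of the statistic.

Allelic ratios pool count-weighted totals (Σ paternal / Σ maternal) rather
than averaging per-gene ratios, which stabilizes low-count genes; the
per-gene distribution is also returned. Genes need ≥ 5 allele-assigned
reads summed across females. The autosomal ratio is reported as an internal
control (expected ≈ 1). `validate_snp_informativeness` flags X genes with
any paternal signal in males (impossible under correct assignment, since
the male X is maternal); flagged genes can be excluded from ratios.

## Numerical and degenerate-input conventions

Zero-variance t-test inputs return (0, 1) when means agree and (±∞, 0)
otherwise. The 2-means split is exact (SSE scan over sorted values), with
deterministic first-minimum tie-breaking. TMM returns factor 1 when no
genes survive trimming or the sample is its own reference. Per-gene tracks
are clipped to a [−2, 4.5] log₂ display range. Division guards raise
validation errors (zero autosomal totals, zero maternal counts) rather than
producing infinities.

## Problem sizes

Defaults follow the emulated study: 20 embryos per (stage, sex, genotype)
for the main design and 10 per sex at E3.5 for the hybrid allelic
experiment, over a ~15,900-gene annotation. At these sizes a full
simulate–preprocess–analyze cycle takes a few seconds on one CPU; the test
suite and the acceptance script each run in well under a minute.

## Known limitations

* Chromosome-level only; no escape-gene or region-level modeling.
* The silencing estimator assumes the generator's multiplicative dosage
  model; on real data, gene-specific escape and imprinting would bias
  σ̂ low in ways the simulation cannot reveal.
* Sex assignment presumes a mixed-sex dataset; single-sex datasets are
  conservatively left unassigned.
* The TMM implementation matches the published trim-and-weight definition
  but not every edge-case heuristic of any particular software release.
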