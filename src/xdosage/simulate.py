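"""Synthetic single-embryo RNA-seq generator.

Emulates the study design the analysis assumes: single whole-embryo
libraries across seven pre/peri-implantation stages (plus optional
trophoblast outgrowths), male and female embryos of WT, RlimKO, XistKO or
B6/CAST hybrid genotype, a mouse-like karyotype (19 autosomes, X, Y, MT),
and negative-binomial count noise over variable library sizes.

The biology is encoded in three per-stage trajectories:

* ``upregulation_trajectory`` ``u_s`` — a multiplier on every *active* X
  allele in both sexes, rising linearly from 1.0 at the 4-cell stage to
  1.58 at E4.5 (progressive X/A upregulation).
* ``silencing_trajectories`` ``sigma(geno, s)`` — the fraction of paternal-X
  expression lost at each stage.  The WT default reaches 0.97 by E4.5
  (near-complete imprinted X inactivation); RlimKO tracks WT through E3.0
  and then plateaus (silencing cannot be maintained without Rlim); XistKO
  stays at the Xist-independent floor.
* ``xist_profiles`` — female *Xist* expression (in cpm), peaking at E3.5
  in WT and decaying after E3.0 in RlimKO.

A small Xist-independent repression of the paternal X (default 0.10)
applies to every female genotype from the 4-cell stage; the effective
silencing at a stage is ``max(xist_independent_silencing, sigma(geno, s))``,
so early female/male dosage sits slightly below two-fold.

Expected counts: for gene ``g`` with per-kilobase expression level
``theta_g`` (log-normal) and length ``len_g``, an autosomal gene has rate
``theta_g * len_g``; an X-linked gene has rate ``theta_g * len_g * b * u_s``
in males and ``theta_g * len_g * b * u_s * (2 - sigma_eff)`` in females,
where ``b`` is ``baseline_x_factor``.  The X-linked ``theta`` draws are
rescaled so that the realized mean X level over ordinary X genes equals
``b`` times the mean autosomal level exactly — the configured dosage is the
dataset's ground truth, not merely its expectation.  Rates are converted to
per-embryo means by scaling to a log-normal library size, and counts are
drawn NB with variance ``mu + dispersion * mu**2`` (gamma-Poisson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import (
    AUTOSOMES,
    STAGES,
    TROPHOBLAST,
    Y_MARKER_GENES,
    AllelicCounts,
    ConfigError,
)

#: Per-stage multiplier on active-X alleles (both sexes), linear 1.0 -> 1.58.
DEFAULT_UPREGULATION: tuple[float, ...] = tuple(
    float(v) for v in np.round(np.linspace(1.0, 1.58, len(STAGES)), 6)
)

#: Fraction of paternal-X expression silenced, per genotype per stage.
DEFAULT_SILENCING: Mapping[str, tuple[float, ...]] = {
    "WT": (0.00, 0.10, 0.25, 0.40, 0.50, 0.75, 0.97),
    # tracks WT through E3.0, then silencing cannot be maintained
    "RlimKO": (0.00, 0.10, 0.25, 0.40, 0.40, 0.40, 0.40),
    # Xist-independent partial silencing only
    "XistKO": (0.10,) * 7,
    # B6/CAST hybrids are WT for both Rlim and Xist
    "hybrid": (0.00, 0.10, 0.25, 0.40, 0.50, 0.75, 0.97),
}

#: Female Xist expression per stage, in expected cpm.
DEFAULT_XIST_CPM: Mapping[str, tuple[float, ...]] = {
    "WT": (20.0, 250.0, 500.0, 800.0, 1000.0, 900.0, 800.0),
    "RlimKO": (20.0, 250.0, 500.0, 800.0, 400.0, 150.0, 60.0),
    "XistKO": (1.0,) * 7,
    "hybrid": (20.0, 250.0, 500.0, 800.0, 1000.0, 900.0, 800.0),
}

_MALE_XIST_CPM = 0.5
_TSIX_CPM = 0.2           # locus is dominated by Xist; Tsix is near-silent
_Y_MARKER_CPM = 40.0      # per marker gene, males only
_RLIM_KO_RESIDUAL = 0.02  # floxed-exon deletion leaves a residual transcript
_N_RRNA = 5
_RRNA_BOOST = 10.0
_MT_BOOST = 15.0


def _default_genes_per_chromosome() -> dict[str, int]:
    # autosomes span roughly 400-1200 annotated expressed genes, larger
    # chromosomes first, mirroring mouse gene-count ordering
    per_autosome = np.round(np.linspace(1200, 400, 19)).astype(int)
    table = {c: int(n) for c, n in zip(AUTOSOMES, per_autosome)}
    table["X"] = 700
    table["Y"] = len(Y_MARKER_GENES)
    table["MT"] = 13
    return table


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults encode the calibration the analysis is meant to recover:
    ``baseline_x_factor=0.49`` (single active X expresses ~half the
    autosomal per-gene mean at the 4-cell stage), upregulation to 1.58-fold
    by E4.5, and the WT/RlimKO/XistKO silencing trajectories above.
    """

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    include_trophoblast: bool = False
    n_embryos: int = 20
    genotypes: tuple[str, ...] = ("WT", "RlimKO")
    n_genes_per_chromosome: Mapping[str, int] = field(
        default_factory=_default_genes_per_chromosome
    )
    baseline_x_factor: float = 0.49
    upregulation_trajectory: tuple[float, ...] = DEFAULT_UPREGULATION
    silencing_trajectories: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SILENCING)
    )
    xist_independent_silencing: float = 0.10
    xist_profiles: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_XIST_CPM)
    )
    dispersion: float = 0.3
    lib_size_median: float = 5e5
    lib_size_sigma: float = 0.35
    allelic_mode: bool = False
    informative_fraction: float = 0.35
    expression_sigma: float = 0.8
    length_median_bp: float = 2000.0
    length_sigma: float = 0.6

    def __post_init__(self) -> None:
        n = len(self.stages)
        if len(self.upregulation_trajectory) not in (n, len(STAGES)):
            raise ConfigError(
                "upregulation_trajectory must cover every configured stage"
            )
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        for geno in self.genotypes:
            sil = self._trajectory(self.silencing_trajectories, geno, "silencing")
            if any(not (0.0 <= s <= 1.0) for s in sil):
                raise ConfigError(f"silencing fractions for {geno!r} must be in [0,1]")
            self._trajectory(self.xist_profiles, geno, "xist_profile")
        if any(u <= 0 for u in self.upregulation_trajectory):
            raise ConfigError("upregulation multipliers must be > 0")
        if self.baseline_x_factor <= 0:
            raise ConfigError("baseline_x_factor must be > 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise ConfigError("informative_fraction must be in (0, 1]")

    # -- trajectory plumbing -------------------------------------------------

    def _trajectory(self, table: Mapping[str, tuple[float, ...]], genotype: str,
                    what: str) -> tuple[float, ...]:
        if genotype not in table:
            raise ConfigError(f"no {what} trajectory for genotype {genotype!r}")
        values = tuple(table[genotype])
        if len(values) == len(self.stages):
            return values
        if len(values) == len(STAGES) and set(self.stages) <= set(STAGES):
            # defaults are declared on the canonical stage list; subset them
            by_stage = dict(zip(STAGES, values))
            return tuple(by_stage[s] for s in self.stages)
        raise ConfigError(
            f"{what} trajectory for {genotype!r} has {len(values)} entries "
            f"but {len(self.stages)} stages are configured"
        )

    def upregulation(self) -> dict[str, float]:
        values = self.upregulation_trajectory
        if len(values) != len(self.stages):
            by_stage = dict(zip(STAGES, values))
            values = tuple(by_stage[s] for s in self.stages)
        out = dict(zip(self.stages, values))
        if self.include_trophoblast:
            out[TROPHOBLAST] = dict(zip(STAGES, self.upregulation_trajectory)).get(
                "E4.5", values[-1]
            )
        return out

    def effective_silencing(self, genotype: str) -> dict[str, float]:
        """Per-stage fraction of Xp expression silenced, floor applied.

        The Xist-independent repression acts as a floor under the
        genotype trajectory, so it is never double-counted.
        """
        sil = self._trajectory(self.silencing_trajectories, genotype, "silencing")
        floor = self.xist_independent_silencing
        out = {s: max(floor, v) for s, v in zip(self.stages, sil)}
        if self.include_trophoblast:
            out[TROPHOBLAST] = 1.0  # E4.5-like with complete Xp silencing
        return out

    def xist_cpm(self, genotype: str) -> dict[str, float]:
        prof = self._trajectory(self.xist_profiles, genotype, "xist_profile")
        out = dict(zip(self.stages, prof))
        if self.include_trophoblast:
            out[TROPHOBLAST] = prof[-1]
        return out

    def all_stages(self) -> tuple[str, ...]:
        return self.stages + ((TROPHOBLAST,) if self.include_trophoblast else ())


def effective_silencing(config: SimulationConfig, genotype: str) -> pd.Series:
    """Ground-truth effective Xp silencing per stage for a genotype."""
    table = config.effective_silencing(genotype)
    return pd.Series(table, name="silencing")


def _build_annotation(config: SimulationConfig, rng: np.random.Generator
                      ) -> pd.DataFrame:
    rows: list[tuple[str, str, str]] = []  # (gene_id, chromosome, role)
    for chrom, n in config.n_genes_per_chromosome.items():
        if chrom == "Y":
            for name in Y_MARKER_GENES[:n]:
                rows.append((name, "Y", "y_marker"))
            for i in range(len(Y_MARKER_GENES), n):
                rows.append((f"gene_Y_{i + 1:04d}", "Y", "none"))
        elif chrom == "X":
            specials = {i: spec for i, spec in
                        zip(range(n // 2, n), (("Xist", "xist"), ("Tsix", "tsix"),
                                               ("Rlim", "rlim")))}
            for i in range(n):
                if i in specials:
                    name, role = specials[i]
                    rows.append((name, "X", role))
                else:
                    rows.append((f"gene_X_{i + 1:04d}", "X", "none"))
        else:
            for i in range(n):
                rows.append((f"gene_{chrom}_{i + 1:04d}", chrom, "none"))
    ann = pd.DataFrame(rows, columns=["gene_id", "chromosome", "role"])
    ann = ann.set_index("gene_id")
    # mark a handful of autosomal genes as residual rRNA, dropped pre-analysis
    auto_none = np.flatnonzero(
        ann["chromosome"].isin(AUTOSOMES).to_numpy() & (ann["role"] == "none").to_numpy()
    )
    for idx in rng.choice(auto_none, size=min(_N_RRNA, auto_none.size), replace=False):
        ann.iloc[idx, ann.columns.get_loc("role")] = "rrna"
    lengths = rng.lognormal(math.log(config.length_median_bp),
                            config.length_sigma, size=len(ann))
    ann["length_bp"] = np.maximum(lengths.round(), 200).astype(np.int64)
    if "Xist" in ann.index:
        ann.loc["Xist", "length_bp"] = 17918
    ann["position"] = ann.groupby("chromosome", sort=False).cumcount() + 1
    return ann


def _gene_levels(config: SimulationConfig, annotation: pd.DataFrame,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-kilobase expression levels theta_g, with the X mean calibrated."""
    theta = rng.lognormal(0.0, config.expression_sigma, size=len(annotation))
    chrom = annotation["chromosome"].to_numpy()
    role = annotation["role"].to_numpy()
    theta[chrom == "MT"] *= _MT_BOOST
    theta[role == "rrna"] *= _RRNA_BOOST
    auto_ord = np.isin(chrom, AUTOSOMES) & (role == "none")
    x_ord = (chrom == "X") & np.isin(role, ("none", "rlim"))
    # pin the realized X/A per-gene level ratio at exactly 1 before the
    # baseline_x_factor is applied, so the configured dosage is exact
    if x_ord.any() and auto_ord.any():
        theta[x_ord] *= theta[auto_ord].mean() / theta[x_ord].mean()
    return theta


def _group_weights(config: SimulationConfig, annotation: pd.DataFrame,
                   theta: np.ndarray, stage: str, sex: str, genotype: str
                   ) -> np.ndarray:
    """Relative expected read rates for one (stage, sex, genotype) group."""
    chrom = annotation["chromosome"].to_numpy()
    role = annotation["role"].to_numpy()
    length = annotation["length_bp"].to_numpy().astype(float)
    u = config.upregulation()[stage]
    sigma = config.effective_silencing(genotype)[stage]
    b = config.baseline_x_factor

    w = theta * length
    on_x = chrom == "X"
    x_dosage = b * u * (1.0 if sex == "male" else (2.0 - sigma))
    w[on_x] *= x_dosage
    if genotype == "RlimKO":
        w[role == "rlim"] *= _RLIM_KO_RESIDUAL
    w[chrom == "Y"] = 0.0
    w[role == "xist"] = 0.0
    w[role == "tsix"] = 0.0
    base_total = w.sum()

    def cpm_weight(cpm: float) -> float:
        return cpm * base_total / 1e6

    if sex == "female":
        w[role == "xist"] = cpm_weight(config.xist_cpm(genotype)[stage])
    else:
        w[role == "xist"] = cpm_weight(_MALE_XIST_CPM)
        w[role == "y_marker"] = cpm_weight(_Y_MARKER_CPM)
    w[role == "tsix"] = cpm_weight(_TSIX_CPM)
    return w


def _nb_counts(mu: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + dispersion * mu**2."""
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    return rng.poisson(lam)


def _iter_groups(config: SimulationConfig):
    for stage in config.all_stages():
        for genotype in config.genotypes:
            for sex in ("female", "male"):
                yield stage, genotype, sex


def simulate_experiment(config: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full single-embryo RNA-seq experiment.

    Returns ``(counts, annotation, samples)``.  The sample table records
    the generating sex in a ``true_sex`` column (the pipeline's ``sex``
    column starts ``unassigned``, as it would on real data).  Fixing the
    seed fixes every output byte.
    """
    root = np.random.SeedSequence(config.seed)
    ss_genes, ss_counts, _ = root.spawn(3)
    rng_genes = np.random.default_rng(ss_genes)
    rng_counts = np.random.default_rng(ss_counts)

    annotation = _build_annotation(config, rng_genes)
    theta = _gene_levels(config, annotation, rng_genes)

    blocks: list[np.ndarray] = []
    meta: list[dict] = []
    sex_tag = {"female": "F", "male": "M"}
    for stage, genotype, sex in _iter_groups(config):
        w = _group_weights(config, annotation, theta, stage, sex, genotype)
        p = w / w.sum()
        lib = rng_counts.lognormal(math.log(config.lib_size_median),
                                   config.lib_size_sigma,
                                   size=config.n_embryos)
        mu = p[:, None] * lib[None, :]
        blocks.append(_nb_counts(mu, config.dispersion, rng_counts))
        for i in range(config.n_embryos):
            meta.append({
                "sample_id": f"{stage}_{genotype}_{sex_tag[sex]}{i + 1:02d}",
                "stage": stage,
                "genotype": genotype,
                "sex": "unassigned",
                "qc_pass": True,
                "effective_lib_size": np.nan,
                "tmm_factor": np.nan,
                "true_sex": sex,
            })

    samples = pd.DataFrame(meta).set_index("sample_id")
    counts = pd.DataFrame(np.hstack(blocks).astype(np.int64),
                          index=annotation.index, columns=samples.index)
    return counts, annotation, samples


def _paternal_share(config: SimulationConfig, annotation: pd.DataFrame,
                    stage: str, sex: str, genotype: str) -> np.ndarray:
    """Expected paternal fraction of allele-assigned reads per gene."""
    chrom = annotation["chromosome"].to_numpy()
    role = annotation["role"].to_numpy()
    p = np.full(len(annotation), 0.5)          # autosomes: bi-allelic 50:50
    p[chrom == "MT"] = 0.0                     # mitochondria are maternal
    if sex == "male":
        p[chrom == "X"] = 0.0                  # single maternal X
        p[chrom == "Y"] = 1.0                  # Y is paternal
    else:
        sigma = config.effective_silencing(genotype)[stage]
        share = (1.0 - sigma) / (2.0 - sigma)  # Xp/(Xm+Xp)
        p[chrom == "X"] = share
        p[role == "xist"] = 0.95               # Xist is transcribed from the Xp
        p[chrom == "Y"] = 0.0
    return p


def simulate_allelic(config: SimulationConfig
                     ) -> tuple[AllelicCounts, pd.DataFrame, pd.DataFrame,
                                pd.DataFrame]:
    """Simulate an allele-resolved (B6/CAST-style) experiment.

    Runs :func:`simulate_experiment` (identical counts for the same config
    and seed), then assigns ``informative_fraction`` of each gene's reads to
    an allele: autosomes split 50:50, female X genes with paternal share
    ``(1-sigma)/(2-sigma)``, male X reads fully maternal.
    """
    if not config.allelic_mode:
        raise ConfigError("simulate_allelic requires allelic_mode=True")
    counts, annotation, samples = simulate_experiment(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    mat = np.zeros(counts.shape, dtype=np.int64)
    pat = np.zeros(counts.shape, dtype=np.int64)
    values = counts.to_numpy()
    col_of = {s: j for j, s in enumerate(counts.columns)}
    for (stage, genotype, sex), group in samples.groupby(
            ["stage", "genotype", "true_sex"], sort=False):
        share = _paternal_share(config, annotation, stage, sex, genotype)
        cols = [col_of[s] for s in group.index]
        block = values[:, cols]
        informative = rng.binomial(block, config.informative_fraction)
        paternal = rng.binomial(informative, share[:, None])
        pat[:, cols] = paternal
        mat[:, cols] = informative - paternal

    allelic = AllelicCounts(
        maternal=pd.DataFrame(mat, index=counts.index, columns=counts.columns),
        paternal=pd.DataFrame(pat, index=counts.index, columns=counts.columns),
    )
    return allelic, counts, annotation, samples


def hybrid_config(seed: int = 0, n_embryos: int = 10,
                  stages: tuple[str, ...] = STAGES, **overrides) -> SimulationConfig:
    """Convenience config for a B6/CAST hybrid allele-resolved experiment."""
    return replace(
        SimulationConfig(seed=seed, n_embryos=n_embryos, stages=stages,
                         genotypes=("hybrid",), allelic_mode=True),
        **overrides,
    )
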