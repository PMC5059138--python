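"""Female/male and X/autosome dosage statistics.

All statistics here are stage-level summaries over QC-passing embryos:

* ``fm_profile`` — mean female/male expression ratio of a gene set,
  computed per gene (mean-of-ratios, matching "averaging ratios per gene
  within each developmental stage") with pooled males across genotypes.
* ``chromosome_log2_fm`` / ``per_gene_fm_track`` — the same ratios per
  chromosome (heatmap form) and per X-linked gene along the chromosome.
* ``stage_fold_changes`` — per-gene log2 fold-change distributions between
  stages, on autosomal-anchored normalized counts.
* ``xa_per_embryo`` and friends — the four X/A upregulation metrics: raw
  total-expression X/A per embryo, per-chromosome profiles relative to the
  4-cell stage, gene-count-normalized chromosome contributions, and
  E4.5/4-cell stage ratios.

Conventions applied throughout: Y-linked genes never enter an F/M or X/A
statistic; *Xist* is excluded from every X-linked aggregate; genes whose
male mean FPKM falls below a floor (default 0.1) are excluded from ratio
statistics to avoid blow-up; male pools include all QC-passing males
regardless of genotype.  Everything is invariant under a common positive
rescaling of all samples' FPKM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    AUTOSOMES,
    ValidationError,
    autosomal_genes,
    stage_sort,
    x_genes,
)

#: Genes with male mean FPKM below this are excluded from ratio statistics.
DEFAULT_MALE_FLOOR = 0.1


# ---------------------------------------------------------------------------
# t-tests

def two_sample_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test; degenerate equal constant inputs give (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 and b.std() == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; identical pairs give (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    if diffs.std(ddof=1) == 0:
        # constant nonzero shift: the statistic diverges
        return float(np.sign(diffs.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# helpers

def _passing(samples: pd.DataFrame) -> pd.DataFrame:
    return samples[samples["qc_pass"]] if "qc_pass" in samples.columns else samples


def _female_cols(samples: pd.DataFrame, genotype: str, stage: str) -> pd.Index:
    tab = _passing(samples)
    return tab.index[(tab["sex"] == "female") & (tab["genotype"] == genotype)
                     & (tab["stage"] == stage)]


def _male_cols(samples: pd.DataFrame, stage: str) -> pd.Index:
    """Pooled males: every QC-passing male regardless of genotype."""
    tab = _passing(samples)
    return tab.index[(tab["sex"] == "male") & (tab["stage"] == stage)]


def _stage_genes(genes: pd.Index, retained: dict[str, pd.Index] | None,
                 stage: str) -> pd.Index:
    if retained is None or stage not in retained:
        return genes
    return genes.intersection(retained[stage])


def fm_gene_ratios(fpkm: pd.DataFrame, samples: pd.DataFrame, genes: pd.Index,
                   stage: str, female_genotype: str,
                   male_floor: float = DEFAULT_MALE_FLOOR,
                   bias_correction: bool = False) -> pd.Series:
    """Per-gene female/male mean-FPKM ratios at one stage.

    ``bias_correction`` divides each ratio by ``1 + var(male mean)/mean^2``,
    a first-order correction of the ratio-estimator bias, used by
    :func:`estimate_silencing` (and left off in :func:`fm_profile`).
    """
    f_cols = _female_cols(samples, female_genotype, stage)
    m_cols = _male_cols(samples, stage)
    if len(f_cols) == 0 or len(m_cols) == 0:
        raise ValidationError(
            f"stage {stage!r}: need >=1 female of genotype {female_genotype!r} "
            f"and >=1 male"
        )
    genes = genes.intersection(fpkm.index)
    f_mean = fpkm.loc[genes, f_cols].mean(axis=1)
    m_mean = fpkm.loc[genes, m_cols].mean(axis=1)
    usable = m_mean >= male_floor
    if not usable.any():
        raise ValidationError(
            f"stage {stage!r}: no genes left after male-mean floor {male_floor}"
        )
    ratios = f_mean[usable] / m_mean[usable]
    if bias_correction and len(m_cols) > 1:
        m_var = fpkm.loc[genes, m_cols].var(axis=1, ddof=1)[usable]
        rel = m_var / (len(m_cols) * m_mean[usable] ** 2)
        ratios = ratios / (1.0 + rel)
    return ratios


def fm_profile(fpkm: pd.DataFrame, samples: pd.DataFrame,
               annotation: pd.DataFrame, female_genotype: str = "WT",
               gene_set: pd.Index | None = None,
               retained: dict[str, pd.Index] | None = None,
               male_floor: float = DEFAULT_MALE_FLOOR,
               compare_genotype: str | None = None) -> pd.DataFrame:
    """Stage-wise mean F/M expression ratio of a gene set.

    The gene set defaults to X-linked genes minus *Xist*.  Each stage's
    value is the mean of per-gene ratios (female mean FPKM of the requested
    genotype over pooled-male mean FPKM); SEM is across genes.  When
    ``compare_genotype`` is given, a two-sided Welch t-test compares the two
    genotypes' per-gene ratio vectors at each stage.
    """
    if gene_set is None:
        gene_set = x_genes(annotation)
    gene_set = gene_set.difference(
        annotation.index[annotation["chromosome"] == "Y"]
    )
    tab = _passing(samples)
    rows = []
    for stage in stage_sort(tab["stage"]):
        genes = _stage_genes(gene_set, retained, stage)
        ratios = fm_gene_ratios(fpkm, samples, genes, stage, female_genotype,
                                male_floor)
        p = np.nan
        if compare_genotype is not None and compare_genotype != female_genotype:
            other = fm_gene_ratios(fpkm, samples, genes, stage,
                                   compare_genotype, male_floor)
            _, p = two_sample_ttest(ratios.to_numpy(), other.to_numpy())
        rows.append({
            "stage": stage,
            "value": float(ratios.mean()),
            "sem": float(ratios.sem()),
            "n_genes": int(len(ratios)),
            "n_female": int(len(_female_cols(samples, female_genotype, stage))),
            "n_male": int(len(_male_cols(samples, stage))),
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("stage")


def chromosome_log2_fm(fpkm: pd.DataFrame, samples: pd.DataFrame,
                       annotation: pd.DataFrame, female_genotype: str = "WT",
                       retained: dict[str, pd.Index] | None = None,
                       male_floor: float = DEFAULT_MALE_FLOOR) -> pd.DataFrame:
    """Chromosome x stage heatmap of log2 mean F/M ratios (Y excluded)."""
    tab = _passing(samples)
    stages = stage_sort(tab["stage"])
    chroms = [c for c in AUTOSOMES + ("X",)
              if (annotation["chromosome"] == c).any()]
    out = pd.DataFrame(np.nan, index=pd.Index(chroms, name="chromosome"),
                       columns=pd.Index(stages, name="stage"))
    for chrom in chroms:
        if chrom == "X":
            genes = x_genes(annotation)
        else:
            genes = annotation.index[annotation["chromosome"] == chrom]
        for stage in stages:
            ratios = fm_gene_ratios(fpkm, samples,
                                    _stage_genes(genes, retained, stage),
                                    stage, female_genotype, male_floor)
            out.loc[chrom, stage] = np.log2(ratios.mean())
    return out


def per_gene_fm_track(fpkm: pd.DataFrame, samples: pd.DataFrame,
                      annotation: pd.DataFrame, stages,
                      female_genotype: str = "WT", chromosome: str = "X",
                      clip: tuple[float, float] = (-2.0, 4.5),
                      retained: dict[str, pd.Index] | None = None,
                      male_floor: float = DEFAULT_MALE_FLOOR) -> pd.DataFrame:
    """Ordered per-gene log2 F/M ratios along a chromosome.

    Genes are ordered by the annotation's ``position`` rank; values are
    clipped to a display range (default [-2, 4.5]).  *Xist* is excluded on
    the X.  Returns one column per requested stage plus the position.
    """
    if chromosome == "X":
        genes = x_genes(annotation)
    else:
        genes = annotation.index[annotation["chromosome"] == chromosome]
    if "position" in annotation.columns:
        genes = genes[np.argsort(annotation.loc[genes, "position"].to_numpy())]
    track = pd.DataFrame(index=genes)
    track["position"] = annotation.loc[genes, "position"] \
        if "position" in annotation.columns else np.arange(1, len(genes) + 1)
    for stage in stages:
        ratios = fm_gene_ratios(fpkm, samples,
                                _stage_genes(pd.Index(genes), retained, stage),
                                stage, female_genotype, male_floor)
        track[stage] = np.clip(np.log2(ratios.reindex(genes)), *clip)
    return track


def stage_fold_changes(counts: pd.DataFrame, samples: pd.DataFrame,
                       annotation: pd.DataFrame, stage_a: str, stage_b: str,
                       female_genotype: str = "WT", chromosome: str = "X",
                       min_cpm: float = 1.0, min_samples: int = 3
                       ) -> tuple[pd.Series, dict]:
    """Per-gene log2 fold changes of ``stage_a`` versus ``stage_b``.

    Genes must have raw cpm > ``min_cpm`` in at least ``min_samples``
    female samples at both stages; expression is normalized to each
    embryo's total autosomal counts before the fold change.  Returns the
    per-gene log2 FC series and a summary (median and quartiles).
    """
    tab = _passing(samples)
    female = tab.index[(tab["sex"] == "female")
                       & (tab["genotype"] == female_genotype)]
    cols = {s: female[tab.loc[female, "stage"] == s] for s in (stage_a, stage_b)}
    for s, c in cols.items():
        if len(c) == 0:
            raise ValidationError(f"no female {female_genotype!r} samples at {s!r}")
    if chromosome == "X":
        genes = x_genes(annotation).intersection(counts.index)
    else:
        genes = annotation.index[
            annotation["chromosome"] == chromosome].intersection(counts.index)

    raw_cpm = (counts * 1e6) / counts.sum(axis=0)
    passing = genes
    for s in (stage_a, stage_b):
        ok = (raw_cpm.loc[genes, cols[s]] > min_cpm).sum(axis=1) >= min_samples
        passing = passing.intersection(genes[ok])

    auto = autosomal_genes(annotation).intersection(counts.index)
    norm = counts / counts.loc[auto].sum(axis=0)
    mean_a = norm.loc[passing, cols[stage_a]].mean(axis=1)
    mean_b = norm.loc[passing, cols[stage_b]].mean(axis=1)
    log2fc = np.log2(mean_a / mean_b)
    log2fc.name = f"log2fc_{stage_a}_vs_{stage_b}"
    summary = {
        "n_genes": int(len(log2fc)),
        "median": float(log2fc.median()),
        "q1": float(log2fc.quantile(0.25)),
        "q3": float(log2fc.quantile(0.75)),
    }
    return log2fc, summary


# ---------------------------------------------------------------------------
# X/A metrics

def xa_per_embryo(fpkm: pd.DataFrame, annotation: pd.DataFrame,
                  exclude_xist: bool = True) -> pd.Series:
    """Total X-linked FPKM over total autosomal FPKM, per embryo."""
    x = x_genes(annotation, exclude_xist=exclude_xist).intersection(fpkm.index)
    a = autosomal_genes(annotation).intersection(fpkm.index)
    a_total = fpkm.loc[a].sum(axis=0)
    if (a_total == 0).any():
        s = a_total.index[a_total == 0][0]
        raise ValidationError(f"sample {s!r} has zero autosomal FPKM")
    xa = fpkm.loc[x].sum(axis=0) / a_total
    xa.name = "x_over_a"
    return xa


def xa_stage_summary(xa: pd.Series, samples: pd.DataFrame,
                     by: tuple[str, ...] = ("sex", "genotype")) -> pd.DataFrame:
    """Stage-wise mean, SEM and n of per-embryo X/A values, per group."""
    tab = _passing(samples).loc[xa.index.intersection(_passing(samples).index)]
    rows = []
    for key, group in tab.groupby(["stage", *by], observed=True):
        vals = xa[group.index]
        rows.append({
            "stage": key[0],
            **dict(zip(by, key[1:])),
            "value": float(vals.mean()),
            "sem": float(vals.sem()) if len(vals) > 1 else np.nan,
            "n": int(len(vals)),
        })
    frame = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(stage_sort(frame["stage"]))}
    return frame.sort_values(["stage", *by],
                             key=lambda c: c.map(order) if c.name == "stage" else c
                             ).reset_index(drop=True)


def _per_embryo_chrom_totals(fpkm: pd.DataFrame, annotation: pd.DataFrame
                             ) -> pd.DataFrame:
    """Summed FPKM per chromosome per embryo (X excludes Xist)."""
    ann = annotation.loc[annotation.index.intersection(fpkm.index)]
    keep = (ann["role"] != "xist")
    ann = ann[keep]
    return fpkm.loc[ann.index].groupby(ann["chromosome"], observed=True).sum()


def _chrom_gene_counts(fpkm: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    ann = annotation.loc[annotation.index.intersection(fpkm.index)]
    ann = ann[ann["role"] != "xist"]
    return ann.groupby("chromosome", observed=True).size()


def chromosome_relative_profile(fpkm: pd.DataFrame, annotation: pd.DataFrame,
                                samples: pd.DataFrame,
                                baseline_stage: str = "4-cell") -> pd.DataFrame:
    """Per-chromosome expression relative to autosomes, anchored at 4-cell.

    Per embryo, each chromosome's total FPKM is divided by the total
    autosomal FPKM; stage means are then divided by the baseline stage's
    value, so every chromosome starts at 1.
    """
    tab = _passing(samples)
    totals = _per_embryo_chrom_totals(fpkm[tab.index], annotation)
    auto = totals.loc[totals.index.isin(AUTOSOMES)].sum(axis=0)
    share = totals.div(auto, axis=1)
    stage_means = share.T.groupby(tab["stage"], observed=True).mean().T
    stage_means = stage_means[stage_sort(stage_means.columns)]
    if baseline_stage not in stage_means.columns:
        raise ValidationError(f"baseline stage {baseline_stage!r} not present")
    rel = stage_means.div(stage_means[baseline_stage], axis=0)
    rel = rel.drop(index=[c for c in ("Y", "MT") if c in rel.index])
    rel.index.name = "chromosome"
    return rel


def chromosome_contribution(fpkm: pd.DataFrame, annotation: pd.DataFrame,
                            samples: pd.DataFrame) -> pd.DataFrame:
    """Gene-count-normalized chromosome contribution, per stage.

    Per embryo: (total FPKM of the chromosome / its gene count) divided by
    (total autosomal FPKM / autosomal gene count); the average autosome is 1
    by construction.  Stage means over embryos are returned.
    """
    tab = _passing(samples)
    totals = _per_embryo_chrom_totals(fpkm[tab.index], annotation)
    n_genes = _chrom_gene_counts(fpkm, annotation)
    auto_chroms = [c for c in totals.index if c in AUTOSOMES]
    auto_total = totals.loc[auto_chroms].sum(axis=0)
    auto_genes = int(n_genes[auto_chroms].sum())
    per_gene = totals.div(n_genes, axis=0)
    contrib = per_gene.div(auto_total / auto_genes, axis=1)
    stage_means = contrib.T.groupby(tab["stage"], observed=True).mean().T
    stage_means = stage_means[stage_sort(stage_means.columns)]
    stage_means = stage_means.drop(
        index=[c for c in ("Y", "MT") if c in stage_means.index])
    stage_means.index.name = "chromosome"
    return stage_means


def xa_gene_normalized(fpkm: pd.DataFrame, annotation: pd.DataFrame,
                       samples: pd.DataFrame) -> pd.DataFrame:
    """Gene-count-normalized X/A per embryo, summarized per (sex, genotype).

    For males this equals the X row of :func:`chromosome_contribution`.
    """
    tab = _passing(samples)
    x = x_genes(annotation).intersection(fpkm.index)
    a = autosomal_genes(annotation).intersection(fpkm.index)
    per_embryo = (fpkm.loc[x, tab.index].sum(axis=0) / len(x)) / \
                 (fpkm.loc[a, tab.index].sum(axis=0) / len(a))
    rows = []
    for (stage, sex, genotype), group in tab.groupby(
            ["stage", "sex", "genotype"], observed=True):
        vals = per_embryo[group.index]
        rows.append({"stage": stage, "sex": sex, "genotype": genotype,
                     "value": float(vals.mean()),
                     "sem": float(vals.sem()) if len(vals) > 1 else np.nan,
                     "n": int(len(vals))})
    frame = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(stage_sort(frame["stage"]))}
    return frame.sort_values(
        ["stage", "sex", "genotype"],
        key=lambda c: c.map(order) if c.name == "stage" else c,
    ).reset_index(drop=True)


def xa_stage_ratio(xa: pd.Series, samples: pd.DataFrame,
                   stage_a: str = "E4.5", stage_b: str = "4-cell") -> dict:
    """Ratio of stage-mean X/A values, with a Welch t-test between stages."""
    tab = _passing(samples)
    a_vals = xa[tab.index[tab["stage"] == stage_a]].dropna()
    b_vals = xa[tab.index[tab["stage"] == stage_b]].dropna()
    if len(a_vals) == 0 or len(b_vals) == 0:
        raise ValidationError(
            f"need samples at both {stage_a!r} and {stage_b!r}")
    t, p = two_sample_ttest(a_vals.to_numpy(), b_vals.to_numpy())
    return {"ratio": float(a_vals.mean() / b_vals.mean()),
            "t": t, "p_value": p,
            "n_a": int(len(a_vals)), "n_b": int(len(b_vals))}


def fm_of_xa(xa: pd.Series, samples: pd.DataFrame,
             female_genotype: str = "WT", stages=None) -> pd.DataFrame:
    """F/M ratio of stage-mean X/A values (females of a genotype vs pooled males)."""
    tab = _passing(samples)
    if stages is None:
        stages = stage_sort(tab["stage"])
    rows = []
    for stage in stages:
        f_cols = _female_cols(samples, female_genotype, stage)
        m_cols = _male_cols(samples, stage)
        if len(f_cols) == 0 or len(m_cols) == 0:
            raise ValidationError(f"stage {stage!r}: need females and males")
        rows.append({"stage": stage,
                     "value": float(xa[f_cols].mean() / xa[m_cols].mean()),
                     "n_female": int(len(f_cols)), "n_male": int(len(m_cols))})
    return pd.DataFrame(rows).set_index("stage")


def estimate_silencing(fpkm: pd.DataFrame, samples: pd.DataFrame,
                       annotation: pd.DataFrame, female_genotype: str = "WT",
                       retained: dict[str, pd.Index] | None = None,
                       male_floor: float = DEFAULT_MALE_FLOOR,
                       bias_correction: bool = True) -> pd.Series:
    """Estimate the effective Xp silencing fraction per stage.

    Under bi-allelic female X expression with a silenced paternal fraction
    ``sigma``, the expected F/M ratio is ``2 - sigma``, so the estimator is
    ``sigma_hat = 2 - mean per-gene F/M``.  A first-order ratio-bias
    correction (see :func:`fm_gene_ratios`) is applied by default, since
    with tens of embryos per group the raw mean-of-ratios overshoots by a
    few percent.
    """
    gene_set = x_genes(annotation)
    tab = _passing(samples)
    out = {}
    for stage in stage_sort(tab["stage"]):
        ratios = fm_gene_ratios(fpkm, samples,
                                _stage_genes(gene_set, retained, stage),
                                stage, female_genotype, male_floor,
                                bias_correction=bias_correction)
        out[stage] = 2.0 - float(ratios.mean())
    return pd.Series(out, name="silencing_estimate")
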