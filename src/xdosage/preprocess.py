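"""From raw counts to analysis-ready expression.

Implements the Methods pipeline: sex assignment from Y-marker and *Xist*
cpm, removal of low-read and sex-unassignable embryos, a stage-wise
low-expression filter, autosomal effective library sizes, within-stage TMM
normalization, cpm/FPKM conversion, and optional random subsampling of
libraries to a fixed depth.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .schema import (
    AUTOSOMES,
    ConfigError,
    NormalizedExpression,
    ValidationError,
    stage_sort,
)

logger = logging.getLogger(__name__)

#: Embryos with fewer total reads than this are removed.
DEFAULT_MIN_TOTAL_READS = 280_000

#: TMM trim fractions: 30% from each M tail, 5% from each A tail, following
#: the published trimmed-mean-of-M-values definition.
TMM_TRIM_M = 0.30
TMM_TRIM_A = 0.05


def total_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million with total (all-gene) library sizes.

    Used before filtering/normalization (sex assignment, the low-expression
    filter); invariant under uniform scaling of a library.
    """
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        totals = totals.replace(0, np.nan)
    return (counts * 1e6).div(totals, axis=1).fillna(0.0)


def _two_means_split(values: np.ndarray) -> tuple[float, float, float]:
    """Exact 1-D 2-means.

    Returns (lower center, upper center, midpoint), where the midpoint lies
    halfway across the gap between the two clusters at the SSE-minimizing
    split (more robust than the midpoint of the centers when the clusters
    have very different spreads, as Xist does across stages).
    """
    v = np.sort(values.astype(float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        c = float(v.mean()) if n else 0.0
        return c, c, c
    cs = np.cumsum(v)
    css = np.cumsum(v * v)
    k = np.arange(1, n)
    sse = (css[:-1] - cs[:-1] ** 2 / k) + (
        (css[-1] - css[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    )
    split = int(np.argmin(sse)) + 1
    c1 = float(cs[split - 1] / split)
    c2 = float((cs[-1] - cs[split - 1]) / (n - split))
    return c1, c2, float((v[split - 1] + v[split]) / 2.0)


def _marker_calls(log_values: np.ndarray, margin: float,
                  min_separation: float) -> tuple[np.ndarray, np.ndarray]:
    """(high, low) boolean calls from a 2-means split with an ambiguity margin."""
    c1, c2, mid = _two_means_split(log_values)
    if c2 - c1 < min_separation:
        # cluster centers closer than min_separation log2 units: the marker
        # does not separate this dataset; call nothing
        none = np.zeros(log_values.shape, dtype=bool)
        return none, none
    return log_values > mid + margin, log_values < mid - margin


def assign_sex(counts: pd.DataFrame, annotation: pd.DataFrame,
               thresholds: tuple[float, float] | None = None,
               xist_blind: bool = False, margin: float = 0.5,
               min_separation: float = 2.0) -> pd.Series:
    """Assign embryo sex from Y-marker and *Xist* expression.

    An embryo is called male when its summed Y-marker cpm is above the Y
    threshold and its *Xist* cpm is below the Xist threshold, female in the
    reverse case, and ``unassigned`` otherwise.  cpm uses total library
    sizes, so the call is invariant to uniform library scaling.

    Default thresholds are derived per dataset.  The Y threshold comes from
    an exact 2-means split of ``log2(1+cpm)`` with an ambiguity margin of
    0.5 log2 units (females carry no Y chromosome, so this split is clean).
    Because *Xist* rises ~50-fold across stages, a global 2-means on it can
    land inside the early-stage female range; the Xist threshold is instead
    derived from the Y-informed populations: just below the 5% quantile of
    the Y-low (putative female) Xist distribution, but never below the
    Y-high (male) median plus the margin.  When the two populations do not
    separate by ``min_separation`` log2 units (e.g. females carrying an
    *Xist* deletion), *Xist* is declared uninformative: males are then
    called from the Y markers alone and no female call is made — use
    ``xist_blind=True`` for such datasets.

    Pass ``thresholds=(y_cpm, xist_cpm)`` to fix both cutoffs explicitly.
    """
    y_markers = annotation.index[annotation["role"] == "y_marker"]
    y_markers = y_markers.intersection(counts.index)
    if len(y_markers) == 0:
        raise ConfigError("annotation declares no role='y_marker' genes")
    xist = annotation.index[annotation["role"] == "xist"].intersection(counts.index)
    if len(xist) == 0 and not xist_blind:
        logger.warning("no Xist gene in annotation; falling back to Y markers only")
        xist_blind = True

    cpm = total_cpm(counts)
    y_cpm = cpm.loc[y_markers].sum(axis=0).to_numpy()
    xist_cpm = (cpm.loc[xist[0]].to_numpy() if len(xist)
                else np.zeros(counts.shape[1]))

    if thresholds is not None:
        y_thr, x_thr = thresholds
        y_high, y_low = y_cpm > y_thr, y_cpm < y_thr
        x_high, x_low = xist_cpm > x_thr, xist_cpm < x_thr
    else:
        log_y = np.log2(1 + y_cpm)
        log_x = np.log2(1 + xist_cpm)
        y_high, y_low = _marker_calls(log_y, margin, min_separation)
        x_high = np.zeros(log_x.shape, dtype=bool)
        x_low = np.ones(log_x.shape, dtype=bool)
        if not xist_blind and y_high.any() and y_low.any():
            sep = np.median(log_x[y_low]) - np.median(log_x[y_high])
            if sep >= min_separation:
                thr = max(float(np.quantile(log_x[y_low], 0.05)) - margin,
                          float(np.median(log_x[y_high])) + margin)
                x_high = log_x > thr
                x_low = ~x_high
            else:
                logger.warning(
                    "assign_sex: Xist does not separate Y-high and Y-low "
                    "samples (%.2f log2 units); females cannot be confirmed "
                    "— consider xist_blind=True", sep)

    if xist_blind:
        male, female = y_high, y_low
    else:
        male = y_high & x_low
        female = y_low & x_high
    sex = np.where(male, "male", np.where(female, "female", "unassigned"))
    return pd.Series(sex, index=counts.columns, name="sex")


def qc_filter(counts: pd.DataFrame, samples: pd.DataFrame,
              min_total_reads: int = DEFAULT_MIN_TOTAL_READS) -> pd.DataFrame:
    """Flag QC failures: strictly fewer reads than the cutoff, or no sex call.

    Both classes are removed together, mirroring the combined removal of
    low-read and sex-unassignable embryos.  Returns an updated sample table.
    """
    out = samples.copy()
    totals = counts.sum(axis=0).reindex(out.index)
    out["qc_pass"] = (totals >= min_total_reads) & (out["sex"] != "unassigned")
    n_fail = int((~out["qc_pass"]).sum())
    if n_fail:
        logger.info("qc_filter: removing %d of %d samples", n_fail, len(out))
    return out


def filter_low_expression(counts: pd.DataFrame, samples: pd.DataFrame,
                          stage: str) -> pd.Index:
    """Stage-wise low-expression filter.

    Keeps a gene iff its cpm is at least 1 in at least ``n`` of the stage's
    QC-passing samples, where ``n`` is the size of the smallest
    (sex, genotype) replicate group within that stage.
    """
    in_stage = samples.index[(samples["stage"] == stage) & samples["qc_pass"]]
    if len(in_stage) == 0:
        raise ValidationError(f"no QC-passing samples at stage {stage!r}")
    groups = samples.loc[in_stage].groupby(["sex", "genotype"], observed=True).size()
    n = int(groups.min())
    cpm = total_cpm(counts[in_stage])
    keep = (cpm >= 1.0).sum(axis=1) >= n
    return counts.index[keep]


def filter_all_stages(counts: pd.DataFrame,
                      samples: pd.DataFrame) -> dict[str, pd.Index]:
    """Apply :func:`filter_low_expression` to every stage present."""
    stages = stage_sort(samples.loc[samples["qc_pass"], "stage"])
    return {s: filter_low_expression(counts, samples, s) for s in stages}


def autosomal_lib_sizes(counts: pd.DataFrame, annotation: pd.DataFrame,
                        retained: pd.Index) -> pd.Series:
    """Effective library sizes: summed retained autosomal counts per sample."""
    autosomal = retained.intersection(
        annotation.index[annotation["chromosome"].isin(AUTOSOMES)]
    )
    sizes = counts.loc[autosomal].sum(axis=0)
    if (sizes == 0).any():
        s = sizes.index[sizes == 0][0]
        raise ValidationError(f"sample {s!r} has zero retained autosomal counts")
    return sizes.astype(np.int64)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 1.0
    po = obs[both] / n_obs
    pr = ref[both] / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (n_obs - obs[both]) / (n_obs * obs[both]) + \
        (n_ref - ref[both]) / (n_ref * ref[both])
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, lib_sizes: pd.Series,
                stage_of: pd.Series, trim_m: float = TMM_TRIM_M,
                trim_a: float = TMM_TRIM_A) -> pd.Series:
    """Trimmed-mean-of-M-values factors, computed independently per stage.

    Within each stage the reference is the sample whose 75th-percentile cpm
    is closest to the stage mean of 75th percentiles; each sample's factor
    is ``2**f`` with ``f`` the inverse-variance-weighted mean of its
    doubly-trimmed M values against that reference (30% trimmed from each M
    tail, 5% from each A tail), and factors are rescaled so their geometric
    mean within the stage is 1.  Stages with fewer than two samples get
    factors of 1 with a warning.
    """
    factors = pd.Series(1.0, index=counts.columns, name="tmm_factor")
    values = counts.to_numpy().astype(float)
    col_of = {s: j for j, s in enumerate(counts.columns)}
    for stage in stage_sort(stage_of):
        cols = stage_of.index[stage_of == stage]
        cols = [c for c in cols if c in col_of]
        if len(cols) < 2:
            logger.warning("tmm_factors: stage %r has <2 samples; factors set to 1",
                           stage)
            continue
        libs = lib_sizes[cols].to_numpy().astype(float)
        block = values[:, [col_of[c] for c in cols]]
        p75 = np.quantile(block / libs[None, :], 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(p75 - p75.mean())))
        ref = block[:, ref_idx]
        n_ref = libs[ref_idx]
        fs = np.array([
            1.0 if j == ref_idx else
            _tmm_pair(block[:, j], ref, libs[j], n_ref, trim_m, trim_a)
            for j in range(len(cols))
        ])
        fs /= np.exp(np.mean(np.log(fs)))
        factors[cols] = fs
    return factors


def compute_cpm(counts: pd.DataFrame, lib_sizes: pd.Series,
                tmm: pd.Series | None = None) -> pd.DataFrame:
    """cpm_gs = counts_gs * 1e6 / (lib_size_s * tmm_factor_s)."""
    denom = lib_sizes.astype(float)
    if tmm is not None:
        denom = denom * tmm
    return (counts * 1e6).div(denom, axis=1)


def compute_fpkm(cpm: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """fpkm_gs = cpm_gs * 1e3 / length_bp_g."""
    lengths = annotation["length_bp"].reindex(cpm.index)
    if lengths.isna().any():
        g = cpm.index[lengths.isna()][0]
        raise ValidationError(f"missing gene length for {g!r}; cannot compute FPKM")
    return cpm.mul(1e3 / lengths.astype(float), axis=0)


def subsample(counts: pd.DataFrame, depth: int,
              seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Randomly subsample each library to ``depth`` reads without replacement.

    Draws a multivariate hypergeometric sample over genes per library, so
    gene proportions are preserved in expectation.  Libraries already at or
    below the target depth are left unchanged (with a warning).
    """
    if depth <= 0:
        raise ValueError("subsample depth must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = counts.copy()
    for col in counts.columns:
        column = counts[col].to_numpy()
        total = int(column.sum())
        if total <= depth:
            if total < depth:
                logger.warning("subsample: %r has %d < %d reads; left unchanged",
                               col, total, depth)
            continue
        out[col] = rng.multivariate_hypergeometric(column, depth)
    return out


def preprocess(counts: pd.DataFrame, annotation: pd.DataFrame,
               samples: pd.DataFrame, *,
               min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
               thresholds: tuple[float, float] | None = None,
               xist_blind: bool = False,
               subsample_depth: int | None = None,
               seed: int = 0) -> NormalizedExpression:
    """Run the full preprocessing chain.

    Order of operations: drop rRNA genes; assign sex; QC-filter (read count
    and sex); optionally subsample libraries; stage-wise low-expression
    filter; autosomal effective library sizes; within-stage TMM on retained
    autosomal genes; cpm/FPKM.  Returns a :class:`NormalizedExpression`
    restricted to QC-passing samples.
    """
    keep_genes = annotation.index[annotation["role"] != "rrna"]
    counts = counts.loc[counts.index.intersection(keep_genes)]

    samples = samples.copy()
    samples["sex"] = assign_sex(counts, annotation, thresholds=thresholds,
                                xist_blind=xist_blind).reindex(samples.index)
    samples = qc_filter(counts, samples, min_total_reads=min_total_reads)
    passing = samples.index[samples["qc_pass"]]
    if len(passing) == 0:
        raise ValidationError("no samples pass QC")
    counts = counts[passing]

    if subsample_depth is not None:
        counts = subsample(counts, subsample_depth, seed=seed)

    retained = filter_all_stages(counts, samples)

    lib_sizes = pd.Series(np.nan, index=passing)
    tmm = pd.Series(1.0, index=passing)
    autosomal = annotation.index[annotation["chromosome"].isin(AUTOSOMES)]
    for stage, genes in retained.items():
        cols = passing[samples.loc[passing, "stage"] == stage]
        stage_auto = genes.intersection(autosomal)
        sizes = autosomal_lib_sizes(counts[cols], annotation, genes)
        lib_sizes[cols] = sizes
        stage_of = samples.loc[cols, "stage"]
        tmm[cols] = tmm_factors(counts.loc[stage_auto, cols], sizes, stage_of)

    samples.loc[passing, "effective_lib_size"] = lib_sizes
    samples.loc[passing, "tmm_factor"] = tmm

    cpm = compute_cpm(counts, lib_sizes, tmm)
    fpkm = compute_fpkm(cpm, annotation)
    return NormalizedExpression(cpm=cpm, fpkm=fpkm,
                                samples=samples, retained=retained)
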