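"""Table schemas, controlled vocabularies and validation.

The pipeline moves a small number of plain-text tables around, all held in
memory as :class:`pandas.DataFrame`/:class:`pandas.Series` with the
conventions documented here:

* **gene annotation** — indexed by ``gene_id``; columns ``chromosome``
  (one of ``"1"``..``"19"``, ``"X"``, ``"Y"``, ``"MT"``, no ``chr`` prefix),
  ``length_bp`` (exonic length used for FPKM), ``role`` (one of
  :data:`ROLES`) and an optional ``position`` (rank of the gene along its
  chromosome, used only for ordered per-gene tracks).
* **count matrix** — genes x samples, non-negative integers, indexed by
  gene id with sample ids as columns.  This is the pipeline's sole primary
  input.
* **sample table** — indexed by ``sample_id``; columns ``stage``,
  ``genotype``, ``sex`` (``male``/``female``/``unassigned``), ``qc_pass``,
  ``effective_lib_size`` (sum of retained autosomal counts) and
  ``tmm_factor``.  Extra columns (e.g. a simulator's ``true_sex``) are
  preserved by all I/O.
* **allelic counts** — a pair of parallel count matrices
  (:class:`AllelicCounts`) holding maternally and paternally assigned reads.

Validators raise :class:`ValidationError` with messages that name the
offending row/column, so malformed inputs fail loudly at the boundary
rather than mid-pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered developmental stages covered by the study design.
STAGES: tuple[str, ...] = ("4-cell", "8-cell", "E2.5", "E3.0", "E3.5", "E4.0", "E4.5")

#: Trophoblast outgrowths, sequenced alongside the staged embryos.
TROPHOBLAST = "troph"

#: Full ordered stage vocabulary accepted in sample tables.
ALL_STAGES: tuple[str, ...] = STAGES + (TROPHOBLAST,)

#: Mouse autosomes; everything used as a normalization anchor lives here.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))

#: All accepted chromosome labels.  "MT" is treated as non-autosomal and is
#: excluded from every autosomal total (organelle copy number would otherwise
#: leak into effective library sizes).
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y", "MT")

#: Special gene roles the analysis needs to know about.
ROLES: tuple[str, ...] = ("none", "xist", "tsix", "rlim", "y_marker", "rrna")

#: The seven Y-linked genes used for sex assignment.
Y_MARKER_GENES: tuple[str, ...] = (
    "Ddx3y", "Eif2s3y", "Kdm5d", "Usp9y", "Uty", "Zfy1", "Zfy2",
)

SEXES: tuple[str, ...] = ("male", "female", "unassigned")


class ValidationError(ValueError):
    """An input table violates its documented schema."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""


@dataclass
class AllelicCounts:
    """Maternal/paternal read counts per gene per sample.

    Both matrices share index (genes) and columns (samples); their sum is
    the allele-assignable ("informative") fraction of each gene's reads and
    is bounded above by the total count matrix.
    """

    maternal: pd.DataFrame
    paternal: pd.DataFrame

    def informative(self) -> pd.DataFrame:
        """Total allele-assigned reads per gene per sample."""
        return self.maternal + self.paternal


@dataclass
class NormalizedExpression:
    """Analysis-ready expression produced by :func:`xdosage.preprocess.preprocess`.

    ``cpm``/``fpkm`` cover all analysed (non-rRNA) genes for every
    QC-passing sample; ``retained`` maps each stage to the gene set that
    passed the stage-wise low-expression filter, and downstream statistics
    restrict themselves to that set.  ``samples`` carries the updated sex,
    QC flags, effective (autosomal) library sizes and TMM factors.
    """

    cpm: pd.DataFrame
    fpkm: pd.DataFrame
    samples: pd.DataFrame
    retained: dict[str, pd.Index] = field(default_factory=dict)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a gene annotation table.

    Returns a copy with the ``role`` column filled in ("none" where absent)
    and chromosome labels as strings.
    """
    ann = annotation.copy()
    _check_unique(ann.index, "gene ids")
    for col in ("chromosome", "length_bp"):
        if col not in ann.columns:
            raise ValidationError(f"annotation is missing required column {col!r}")
    ann["chromosome"] = ann["chromosome"].astype(str)
    bad = ~ann["chromosome"].isin(CHROMOSOMES)
    if bad.any():
        g = ann.index[bad][0]
        raise ValidationError(
            f"unknown chromosome {ann.loc[g, 'chromosome']!r} for gene {g!r}"
        )
    lengths = pd.to_numeric(ann["length_bp"], errors="coerce")
    if lengths.isna().any() or (lengths < 1).any() or (lengths % 1 != 0).any():
        g = ann.index[(lengths.isna()) | (lengths < 1) | (lengths % 1 != 0)][0]
        raise ValidationError(f"length_bp must be a positive integer (gene {g!r})")
    ann["length_bp"] = lengths.astype(np.int64)
    if "role" not in ann.columns:
        ann["role"] = "none"
    ann["role"] = ann["role"].fillna("none").replace("", "none").astype(str)
    bad_role = ~ann["role"].isin(ROLES)
    if bad_role.any():
        g = ann.index[bad_role][0]
        raise ValidationError(f"unknown role {ann.loc[g, 'role']!r} for gene {g!r}")
    if (ann["role"] == "xist").sum() > 1:
        raise ValidationError("at most one gene may carry role 'xist'")
    has_y = (ann["chromosome"] == "Y").any()
    if has_y and not ((ann["role"] == "y_marker").any()):
        raise ValidationError(
            "annotation has Y-linked genes but no role='y_marker' genes; "
            "sex assignment needs a non-empty Y marker set"
        )
    return ann


def validate_counts(
    counts: pd.DataFrame, annotation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Validate a gene x sample count matrix.

    Entries must be non-negative integers; gene and sample ids unique; when
    an annotation is supplied every gene must resolve in it.
    """
    _check_unique(counts.index, "gene ids")
    _check_unique(pd.Index(counts.columns), "sample ids")
    for col in counts.columns:
        values = counts[col]
        if not pd.api.types.is_integer_dtype(values):
            numeric = pd.to_numeric(values, errors="coerce")
            if numeric.isna().any() or (numeric % 1 != 0).any():
                bad = counts.index[numeric.isna() | (numeric % 1 != 0)][0]
                raise ValidationError(
                    f"non-integer entry at gene {bad!r}, sample {col!r}"
                )
            counts = counts.copy()
            counts[col] = numeric.astype(np.int64)
        if (counts[col] < 0).any():
            bad = counts.index[counts[col] < 0][0]
            raise ValidationError(f"negative count at gene {bad!r}, sample {col!r}")
    counts = counts.astype(np.int64)
    if annotation is not None:
        missing = counts.index.difference(annotation.index)
        if len(missing):
            raise ValidationError(
                f"genes absent from annotation: {missing.tolist()[:5]}"
            )
    return counts


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table, filling optional columns with defaults."""
    tab = samples.copy()
    _check_unique(tab.index, "sample ids")
    if "stage" not in tab.columns or "genotype" not in tab.columns:
        raise ValidationError("sample table needs 'stage' and 'genotype' columns")
    tab["stage"] = tab["stage"].astype(str)
    bad = ~tab["stage"].isin(ALL_STAGES)
    if bad.any():
        s = tab.index[bad][0]
        raise ValidationError(
            f"unknown stage {tab.loc[s, 'stage']!r} for sample {s!r}; "
            f"expected one of {list(ALL_STAGES)}"
        )
    if "sex" not in tab.columns:
        tab["sex"] = "unassigned"
    bad_sex = ~tab["sex"].isin(SEXES)
    if bad_sex.any():
        s = tab.index[bad_sex][0]
        raise ValidationError(f"unknown sex {tab.loc[s, 'sex']!r} for sample {s!r}")
    if "qc_pass" not in tab.columns:
        tab["qc_pass"] = True
    tab["qc_pass"] = tab["qc_pass"].astype(bool)
    if "effective_lib_size" not in tab.columns:
        tab["effective_lib_size"] = np.nan
    if "tmm_factor" not in tab.columns:
        tab["tmm_factor"] = np.nan
    tmm = pd.to_numeric(tab["tmm_factor"], errors="coerce")
    if ((tmm <= 0) & tmm.notna()).any():
        s = tab.index[(tmm <= 0) & tmm.notna()][0]
        raise ValidationError(f"tmm_factor must be > 0 when set (sample {s!r})")
    return tab


def validate_allelic(
    allelic: AllelicCounts, counts: pd.DataFrame | None = None
) -> AllelicCounts:
    """Validate an allele-resolved count pair (optionally against totals)."""
    mat, pat = allelic.maternal, allelic.paternal
    if not mat.index.equals(pat.index) or not mat.columns.equals(pat.columns):
        raise ValidationError("maternal and paternal matrices must be parallel")
    mat = validate_counts(mat)
    pat = validate_counts(pat)
    if counts is not None:
        total = mat + pat
        aligned = counts.loc[total.index, total.columns]
        if (total > aligned).any().any():
            over = total.gt(aligned)
            g = total.index[over.any(axis=1)][0]
            raise ValidationError(
                f"allelic counts exceed total counts (first offender: gene {g!r})"
            )
    return AllelicCounts(maternal=mat, paternal=pat)


def stage_sort(stages) -> list[str]:
    """Sort stage labels by the canonical developmental order."""
    order = {s: i for i, s in enumerate(ALL_STAGES)}
    return sorted(set(stages), key=lambda s: order.get(s, len(order)))


def autosomal_genes(annotation: pd.DataFrame) -> pd.Index:
    """Genes on chromosomes 1-19 (X, Y and MT excluded)."""
    return annotation.index[annotation["chromosome"].isin(AUTOSOMES)]


def x_genes(annotation: pd.DataFrame, exclude_xist: bool = True) -> pd.Index:
    """X-linked genes, by default minus *Xist* (excluded from all X aggregates)."""
    mask = annotation["chromosome"] == "X"
    if exclude_xist:
        mask &= annotation["role"] != "xist"
    return annotation.index[mask]
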