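"""Allele-specific Xp/Xm expression from allele-resolved counts.

Consumes maternal/paternal count matrices for hybrid (e.g. B6 x CAST)
crosses, where strain SNPs let a fraction of reads be assigned to an
allele.  SNP calling itself is upstream; this module quantifies paternal
versus maternal X expression in females (the direct readout of imprinted
X inactivation) and validates gene-level allele assignments against male
embryos, whose single X is maternal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    AllelicCounts,
    ValidationError,
    autosomal_genes,
    x_genes,
)


@dataclass
class AllelicRatioResult:
    """Pooled and per-gene paternal/maternal expression ratios.

    ``ratio`` is count-weighted (total paternal over total maternal reads,
    which stabilizes low-count genes); ``per_gene`` holds the per-gene
    ratio distribution; ``autosomal_ratio`` is the internal control,
    expected to be ~1 for a bi-allelic genome.
    """

    ratio: float
    per_gene: pd.Series
    autosomal_ratio: float
    n_genes: int
    n_samples: int


def _informative_genes(allelic: AllelicCounts, genes: pd.Index,
                       cols: pd.Index, min_informative: int) -> pd.Index:
    info = (allelic.maternal.loc[genes, cols]
            + allelic.paternal.loc[genes, cols]).sum(axis=1)
    return genes[info >= min_informative]


def allelic_ratio(allelic: AllelicCounts, annotation: pd.DataFrame,
                  samples: pd.DataFrame, chromosome: str = "X",
                  min_informative: int = 5, exclude_xist: bool = True,
                  exclude_genes: pd.Index | None = None) -> AllelicRatioResult:
    """Paternal/maternal expression ratio in female embryos.

    Pools reads over genes on ``chromosome`` (X by default, minus *Xist*)
    with at least ``min_informative`` allele-assigned reads summed across
    the selected females; reports the count-weighted paternal/maternal
    ratio, the per-gene distribution, and the autosomal control ratio.
    """
    tab = samples[samples["qc_pass"]] if "qc_pass" in samples.columns else samples
    females = tab.index[tab["sex"] == "female"]
    females = females.intersection(allelic.maternal.columns)
    if len(females) == 0:
        raise ValidationError("no QC-passing female samples for allelic ratios")

    if chromosome == "X":
        genes = x_genes(annotation, exclude_xist=exclude_xist)
    else:
        genes = annotation.index[annotation["chromosome"] == chromosome]
    genes = genes.intersection(allelic.maternal.index)
    if exclude_genes is not None:
        genes = genes.difference(exclude_genes)
    genes = _informative_genes(allelic, genes, females, min_informative)
    if len(genes) == 0:
        raise ValidationError(
            f"no genes on chromosome {chromosome!r} with >= {min_informative} "
            "informative reads"
        )

    mat = allelic.maternal.loc[genes, females].sum(axis=1)
    pat = allelic.paternal.loc[genes, females].sum(axis=1)
    if mat.sum() == 0:
        raise ValidationError("zero maternal counts; cannot form ratio")
    per_gene = (pat / mat.where(mat > 0)).rename("paternal_over_maternal")

    auto = _informative_genes(
        allelic, autosomal_genes(annotation).intersection(allelic.maternal.index),
        females, min_informative,
    )
    auto_mat = float(allelic.maternal.loc[auto, females].to_numpy().sum())
    auto_pat = float(allelic.paternal.loc[auto, females].to_numpy().sum())
    return AllelicRatioResult(
        ratio=float(pat.sum() / mat.sum()),
        per_gene=per_gene,
        autosomal_ratio=auto_pat / auto_mat if auto_mat > 0 else np.nan,
        n_genes=int(len(genes)),
        n_samples=int(len(females)),
    )


def validate_snp_informativeness(allelic: AllelicCounts,
                                 annotation: pd.DataFrame,
                                 samples: pd.DataFrame,
                                 min_flag_reads: int = 1) -> pd.DataFrame:
    """Flag X-linked genes with paternal signal in male embryos.

    Males carry a single, maternally inherited X, so any paternally
    assigned X-linked reads in males indicate allele mis-assignment; such
    genes should be excluded from ratios (pass the flagged index as
    ``exclude_genes`` to :func:`allelic_ratio`).  Returns a per-gene report
    with male paternal/informative read totals and a ``flagged`` column.
    """
    tab = samples[samples["qc_pass"]] if "qc_pass" in samples.columns else samples
    males = tab.index[tab["sex"] == "male"].intersection(allelic.maternal.columns)
    genes = x_genes(annotation, exclude_xist=False).intersection(
        allelic.maternal.index)
    if len(males) == 0:
        return pd.DataFrame(
            {"male_paternal": pd.Series(0, index=genes, dtype=np.int64),
             "male_informative": 0, "flagged": False},
            index=genes,
        )
    pat = allelic.paternal.loc[genes, males].sum(axis=1)
    info = (allelic.maternal.loc[genes, males]
            + allelic.paternal.loc[genes, males]).sum(axis=1)
    report = pd.DataFrame({
        "male_paternal": pat.astype(np.int64),
        "male_informative": info.astype(np.int64),
        "flagged": pat >= min_flag_reads,
    })
    report.index.name = "gene_id"
    return report
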