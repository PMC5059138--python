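"""Readers and writers for the pipeline's plain-text tables.

Tab-separated UTF-8 is the canonical interchange format; MatrixMarket is
supported for count matrices only (with ``<base>.genes.txt`` /
``<base>.samples.txt`` sidecar id lists).  Every writer/reader pair
round-trips exactly.  Lines starting with ``#`` are treated as comments, so
pipeline outputs can carry a provenance header without breaking re-reads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .schema import (
    AllelicCounts,
    ValidationError,
    validate_allelic,
    validate_annotation,
    validate_counts,
    validate_samples,
)

_SAMPLE_COLUMNS = [
    "stage",
    "genotype",
    "sex",
    "qc_pass",
    "effective_lib_size",
    "tmm_factor",
]


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: malformed or empty table ({exc})") from exc
    if frame.index.name is None and frame.empty:
        raise ValidationError(f"{path}: empty table")
    frame.index = frame.index.astype(str)
    return frame


def _header_ids(path: Path) -> list[str]:
    """Raw header fields, before pandas mangles duplicate column names."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                return line.rstrip("\n").split("\t")
    raise ValidationError(f"{path}: empty file")


def _mtx_base(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".mtx" else path


def read_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene x sample count matrix (TSV, or MatrixMarket + sidecars).

    The TSV layout is a header row of sample ids and a first column of gene
    ids.  Returns a validated integer DataFrame preserving input order.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        header = _header_ids(path)
        samples = header[1:]
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise ValidationError(f"{path}: duplicate sample ids {dupes[:5]}")
        counts = _read_tsv(path)
        counts.index.name = "gene_id"
    elif fmt == "mtx":
        base = _mtx_base(path)
        genes = Path(f"{base}.genes.txt").read_text().split()
        samples = Path(f"{base}.samples.txt").read_text().split()
        matrix = scipy.io.mmread(path)
        dense = np.asarray(
            matrix.todense() if scipy.sparse.issparse(matrix) else matrix
        )
        counts = pd.DataFrame(dense, index=pd.Index(genes, name="gene_id"),
                              columns=samples)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path, fmt: str | None = None,
                 header_comment: str | None = None) -> None:
    """Write a count matrix as TSV (default) or MatrixMarket."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        _write_table(counts, path, index_name="gene_id",
                     header_comment=header_comment)
    elif fmt == "mtx":
        base = _mtx_base(path)
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.to_numpy()))
        Path(f"{base}.genes.txt").write_text("\n".join(counts.index) + "\n")
        Path(f"{base}.samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def _write_table(frame: pd.DataFrame, path: Path, index_name: str,
                 header_comment: str | None = None) -> None:
    out = frame.copy()
    out.index.name = index_name
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chromosome, length_bp, role, ...)."""
    ann = _read_tsv(Path(path))
    ann.index.name = "gene_id"
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path,
                     header_comment: str | None = None) -> None:
    lead = [c for c in ("chromosome", "length_bp", "role", "position")
            if c in annotation.columns]
    rest = [c for c in annotation.columns if c not in lead]
    _write_table(annotation[lead + rest], Path(path), "gene_id", header_comment)


def read_samples(path) -> pd.DataFrame:
    """Read a sample metadata TSV."""
    tab = _read_tsv(Path(path))
    tab.index.name = "sample_id"
    return validate_samples(tab)


def write_samples(samples: pd.DataFrame, path,
                  header_comment: str | None = None) -> None:
    lead = [c for c in _SAMPLE_COLUMNS if c in samples.columns]
    rest = [c for c in samples.columns if c not in lead]
    _write_table(samples[lead + rest], Path(path), "sample_id", header_comment)


def read_allelic(maternal_path, paternal_path) -> AllelicCounts:
    """Read a pair of parallel maternal/paternal count matrices."""
    maternal = read_counts(maternal_path)
    paternal = read_counts(paternal_path)
    return validate_allelic(AllelicCounts(maternal=maternal, paternal=paternal))


def write_allelic(allelic: AllelicCounts, maternal_path, paternal_path,
                  header_comment: str | None = None) -> None:
    write_counts(allelic.maternal, maternal_path, header_comment=header_comment)
    write_counts(allelic.paternal, paternal_path, header_comment=header_comment)
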