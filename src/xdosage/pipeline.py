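"""End-to-end orchestration: simulate -> preprocess -> dosage -> allelic.

A :class:`PipelineConfig` captures every knob; :func:`run_pipeline` executes
the requested stages deterministically (fixed seed, no hidden global state)
and writes tidy TSV panel tables plus a machine-readable run manifest.
Every output table carries a ``config_hash`` comment header so results can
be traced back to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .allelic import allelic_ratio, validate_snp_informativeness
from .dosage import (
    chromosome_contribution,
    chromosome_log2_fm,
    chromosome_relative_profile,
    fm_of_xa,
    fm_profile,
    xa_gene_normalized,
    xa_per_embryo,
    xa_stage_ratio,
    xa_stage_summary,
)
from .preprocess import DEFAULT_MIN_TOTAL_READS, preprocess
from .simulate import SimulationConfig, simulate_allelic, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS
    subsample_depth: int | None = None
    xist_blind: bool = False
    male_floor: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        sim = out["simulation"]
        for key in ("n_genes_per_chromosome", "silencing_trajectories",
                    "xist_profiles"):
            sim[key] = {k: (list(v) if isinstance(v, (tuple, list)) else v)
                        for k, v in dict(sim[key]).items()}
        for key in ("stages", "genotypes", "upregulation_trajectory"):
            sim[key] = list(sim[key])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = dict(data.pop("simulation", {}))
        for key in ("stages", "genotypes", "upregulation_trajectory"):
            if key in sim:
                sim[key] = tuple(sim[key])
        for key in ("silencing_trajectories", "xist_profiles"):
            if key in sim:
                sim[key] = {k: tuple(v) for k, v in sim[key].items()}
        return cls(simulation=SimulationConfig(**sim), **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_panels(out: Path, tag: str, tables: dict, header: str) -> list[str]:
    written = []
    for name, frame in tables.items():
        path = out / f"{tag}{name}.tsv"
        io._write_table(frame, path, frame.index.name or "id", header)
        written.append(path.name)
    return written


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the configured pipeline and write all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"config_hash={config.hash()} xdosage={__version__}"
    sim = dataclasses.replace(config.simulation, seed=config.simulation.seed)
    outputs: list[str] = []

    if sim.allelic_mode:
        allelic, counts, annotation, samples = simulate_allelic(sim)
        io.write_allelic(allelic, out / "maternal.tsv", out / "paternal.tsv",
                         header_comment=header)
        outputs += ["maternal.tsv", "paternal.tsv"]
    else:
        allelic = None
        counts, annotation, samples = simulate_experiment(sim)
    io.write_counts(counts, out / "counts.tsv", header_comment=header)
    io.write_annotation(annotation, out / "annotation.tsv", header_comment=header)
    outputs += ["counts.tsv", "annotation.tsv"]

    norm = preprocess(counts, annotation, samples,
                      min_total_reads=config.min_total_reads,
                      xist_blind=config.xist_blind,
                      subsample_depth=config.subsample_depth,
                      seed=config.seed)
    io.write_samples(norm.samples, out / "samples.tsv", header_comment=header)
    io._write_table(norm.cpm, out / "cpm.tsv", "gene_id", header)
    io._write_table(norm.fpkm, out / "fpkm.tsv", "gene_id", header)
    retained_rows = [(stage, gene) for stage, genes in norm.retained.items()
                     for gene in genes]
    retained = pd.DataFrame(retained_rows, columns=["stage", "gene_id"])
    retained.to_csv(out / "retained_genes.tsv", sep="\t", index=False)
    outputs += ["samples.tsv", "cpm.tsv", "fpkm.tsv", "retained_genes.tsv"]

    passing = norm.samples[norm.samples["qc_pass"]]
    female_genotypes = sorted(
        set(passing.loc[passing["sex"] == "female", "genotype"]))
    have_males = (passing["sex"] == "male").any()

    panels: dict[str, "pd.DataFrame"] = {}
    xa = xa_per_embryo(norm.fpkm, annotation)
    panels["xa_per_embryo"] = xa.to_frame()
    panels["xa_stage_summary"] = xa_stage_summary(xa, norm.samples)
    panels["chromosome_contribution"] = chromosome_contribution(
        norm.fpkm, annotation, norm.samples)
    panels["xa_gene_normalized"] = xa_gene_normalized(
        norm.fpkm, annotation, norm.samples)
    males = passing.index[passing["sex"] == "male"]
    male_stages = set(passing.loc[males, "stage"])
    if len(males) and "4-cell" in male_stages:
        panels["chromosome_relative_male"] = chromosome_relative_profile(
            norm.fpkm[males], annotation, norm.samples.loc[males])
    if {"4-cell", "E4.5"} <= male_stages:
        panels["xa_stage_ratio_male"] = pd.DataFrame(
            [xa_stage_ratio(xa[males], norm.samples.loc[males])],
            index=pd.Index(["E4.5_vs_4-cell"], name="comparison"))
    if have_males:
        for genotype in female_genotypes:
            tag = genotype.lower()
            panels[f"fm_profile_{tag}"] = fm_profile(
                norm.fpkm, norm.samples, annotation, female_genotype=genotype,
                retained=norm.retained, male_floor=config.male_floor)
            panels[f"chromosome_log2_fm_{tag}"] = chromosome_log2_fm(
                norm.fpkm, norm.samples, annotation, female_genotype=genotype,
                retained=norm.retained, male_floor=config.male_floor)
            panels[f"fm_of_xa_{tag}"] = fm_of_xa(xa, norm.samples,
                                                 female_genotype=genotype)
    outputs += _write_panels(out, "", panels, header)

    if allelic is not None and have_males and female_genotypes:
        report = validate_snp_informativeness(allelic, annotation, norm.samples)
        flagged = report.index[report["flagged"]]
        result = allelic_ratio(allelic, annotation, norm.samples,
                               exclude_genes=flagged)
        ratios = pd.DataFrame({
            "metric": ["x_paternal_over_maternal", "autosomal_control",
                       "n_genes", "n_samples"],
            "value": [result.ratio, result.autosomal_ratio,
                      result.n_genes, result.n_samples],
        }).set_index("metric")
        io._write_table(ratios, out / "allelic_ratios.tsv", "metric", header)
        io._write_table(report, out / "allelic_validation.tsv", "gene_id", header)
        outputs += ["allelic_ratios.tsv", "allelic_validation.tsv"]

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "xdosage_version": __version__,
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return out
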