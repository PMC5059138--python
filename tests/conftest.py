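"""Shared fixtures: small hand-built tables and a compact simulated dataset."""

import numpy as np
import pandas as pd
import pytest

from xdosage import SimulationConfig


def make_annotation(rows):
    """rows: (gene_id, chromosome, length_bp[, role]) tuples."""
    records = []
    for row in rows:
        gene, chrom, length = row[:3]
        role = row[3] if len(row) > 3 else "none"
        records.append((gene, str(chrom), int(length), role))
    ann = pd.DataFrame(records,
                       columns=["gene_id", "chromosome", "length_bp", "role"])
    return ann.set_index("gene_id")


def make_samples(rows):
    """rows: (sample_id, stage, genotype, sex) tuples; qc_pass defaults True."""
    tab = pd.DataFrame(
        [(s, st, g, sex, True, np.nan, np.nan) for s, st, g, sex in rows],
        columns=["sample_id", "stage", "genotype", "sex", "qc_pass",
                 "effective_lib_size", "tmm_factor"],
    )
    return tab.set_index("sample_id")


@pytest.fixture(scope="session")
def tiny_config():
    """A small but complete study design for fast end-to-end tests."""
    genes = {str(i): 40 for i in range(1, 20)}
    genes.update({"X": 60, "Y": 7, "MT": 5})
    return SimulationConfig(
        seed=1234,
        n_embryos=6,
        genotypes=("WT",),
        n_genes_per_chromosome=genes,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    from xdosage import simulate_experiment

    return simulate_experiment(tiny_config)
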