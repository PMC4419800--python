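"""Shared fixtures: small synthetic worlds and hand-built gene tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import chromstab as cs

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: scaled-down per-chromosome gene counts for fast end-to-end tests
SMALL_COUNTS = {str(i): 60 for i in range(1, 23)} | {"X": 40}


@pytest.fixture
def small_params() -> cs.SyntheticParams:
    return cs.SyntheticParams(seed=11, genes_per_chromosome=SMALL_COUNTS)


@pytest.fixture
def small_table(small_params):
    table, truth = cs.generate_gene_table(small_params)
    return table, truth


def table_from_values(values_by_chrom, karyotype=cs.HUMAN, spacing=1000,
                      **extra_cols) -> cs.GeneTable:
    """Build a GeneTable from {chromosome: [half-life, ...]} with coordinates
    laid out in list order."""
    rows = []
    for chrom, values in values_by_chrom.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "gene_id": f"{chrom}.g{i}",
                    "chromosome": chrom,
                    "strand": "+",
                    "start": spacing * (i + 1),
                    "end": spacing * (i + 1) + 500,
                    "half_life_h": v,
                }
            )
    df = pd.DataFrame(rows)
    for name, mapping in extra_cols.items():
        df[name] = [mapping[gid] for gid in df["gene_id"]]
    return cs.GeneTable(df, karyotype=karyotype)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
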