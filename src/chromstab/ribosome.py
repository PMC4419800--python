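"""Ribosome density from paired ribo-seq/RNA-seq count tables.

Density (translational efficiency) is the ratio of the ribo-seq RPKM to the
RNA-seq RPKM of the same gene, computed after stringent count/RPKM cutoffs
(strict inequalities: ribo count > 10, RNA count > 50, ribo RPKM > 2, RNA
RPKM > 5) and removal of an exclusion list (poly(A)-minus histone genes,
whose RNA level a poly(A)-selected library cannot measure). Library totals
default to the column sums of the input count tables; that choice cancels in
the cross-chromosome comparison of the density ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError
from .karyotype import HUMAN, Karyotype
from .stats import (
    ChromosomeSummary,
    TestResult,
    chromosome_summary,
    pairwise_chromosome_tests,
    x_vs_autosomes_test,
)
from .tables import GeneTable

__all__ = [
    "FilterThresholds",
    "compute_rpkm",
    "build_ribo_table",
    "apply_filters",
    "add_density",
    "density_by_chromosome",
    "DensityByChromosome",
]

logger = logging.getLogger(__name__)

#: fixed rule order used for removal-count attribution
RULE_ORDER = ("ribo_count", "rna_count", "ribo_rpkm", "rna_rpkm", "exclusion")


@dataclass(frozen=True)
class FilterThresholds:
    ribo_count_gt: float = 10
    rna_count_gt: float = 50
    ribo_rpkm_gt: float = 2.0
    rna_rpkm_gt: float = 5.0
    exclusion: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("ribo_count_gt", "rna_count_gt", "ribo_rpkm_gt", "rna_rpkm_gt"):
            if getattr(self, name) < 0:
                raise InputError(f"threshold {name} must be non-negative")


def compute_rpkm(count: float, length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_bp <= 0:
        raise InputError("length_bp must be positive")
    if total_mapped <= 0:
        raise InputError("total_mapped must be positive")
    return count / (length_bp / 1e3) / (total_mapped / 1e6)


def build_ribo_table(
    gene_table: GeneTable,
    ribo_counts: pd.Series,
    rna_counts: pd.Series,
    ribo_total: float | None = None,
    rna_total: float | None = None,
) -> pd.DataFrame:
    """Join counts onto the gene table and compute both RPKM columns.

    ``ribo_counts``/``rna_counts`` are indexed by gene_id. Library totals
    default to the column sums. Gene length is the table's mrna_length_bp.
    """
    df = gene_table.df[["gene_id", "chromosome", "mrna_length_bp"]].copy()
    df = df.rename(columns={"mrna_length_bp": "length_bp"})
    df["ribo_count"] = df["gene_id"].map(ribo_counts)
    df["rna_count"] = df["gene_id"].map(rna_counts)
    df = df.dropna(subset=["ribo_count", "rna_count", "length_bp"])
    if df.empty:
        raise InputError("no genes shared between gene table and count tables")
    ribo_total = float(ribo_total if ribo_total is not None else df["ribo_count"].sum())
    rna_total = float(rna_total if rna_total is not None else df["rna_count"].sum())
    if ribo_total <= 0 or rna_total <= 0:
        raise InputError("library totals must be positive")
    length = df["length_bp"].to_numpy(dtype=float)
    df["ribo_rpkm"] = df["ribo_count"].to_numpy(float) / (length / 1e3) / (ribo_total / 1e6)
    df["rna_rpkm"] = df["rna_count"].to_numpy(float) / (length / 1e3) / (rna_total / 1e6)
    return df.reset_index(drop=True)


def apply_filters(
    records: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records passing every cutoff (strict >) and not excluded.

    Removal counts attribute each removed record to the first failing rule
    in the fixed order ribo_count, rna_count, ribo_rpkm, rna_rpkm,
    exclusion, so the per-rule tally is reproducible.
    """
    fails = {
        "ribo_count": ~(records["ribo_count"] > thresholds.ribo_count_gt),
        "rna_count": ~(records["rna_count"] > thresholds.rna_count_gt),
        "ribo_rpkm": ~(records["ribo_rpkm"] > thresholds.ribo_rpkm_gt),
        "rna_rpkm": ~(records["rna_rpkm"] > thresholds.rna_rpkm_gt),
        "exclusion": records["gene_id"].isin(thresholds.exclusion),
    }
    removal_counts: dict[str, int] = {}
    attributed = pd.Series(False, index=records.index)
    for rule in RULE_ORDER:
        newly = fails[rule] & ~attributed
        removal_counts[rule] = int(newly.sum())
        attributed |= fails[rule]
    kept = records[~attributed].reset_index(drop=True)
    if kept.empty:
        logger.info("apply_filters removed every record")
    return kept, removal_counts


def add_density(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene density = ribo RPKM / RNA RPKM (records must be filtered)."""
    zero = records["rna_rpkm"] == 0
    if zero.any():
        gene = records.loc[zero, "gene_id"].iloc[0]
        raise ComputationError(
            f"rna_rpkm is zero for gene {gene!r}; filter records first"
        )
    out = records.copy()
    out["density"] = out["ribo_rpkm"] / out["rna_rpkm"]
    return out


@dataclass
class DensityByChromosome:
    summaries: list[ChromosomeSummary]
    xa_test: TestResult
    xa_test_corrected: TestResult
    pairwise: pd.DataFrame = field(repr=False)
    xa_ratio: float = float("nan")


def density_by_chromosome(
    records: pd.DataFrame,
    karyotype: Karyotype = HUMAN,
    correction: str = "bonferroni",
) -> DensityByChromosome:
    """Per-chromosome density summaries plus both flavours of X-vs-A test:
    the single pooled comparison and the multiple-comparison-corrected
    variant alongside the full pairwise matrix."""
    if "density" not in records.columns:
        raise InputError("records carry no density column; call add_density")
    table = GeneTable(
        records[["gene_id", "chromosome", "density"]].copy(),
        dataset_label="ribosome-density",
        karyotype=karyotype,
    )
    x_n = len(table.x_values("density"))
    a_n = len(table.autosomal_values("density"))
    if x_n == 0 or a_n == 0:
        raise InputError("a compartment is empty after filtering")
    summaries = chromosome_summary(table, "density")
    pairwise = pairwise_chromosome_tests(table, "density", correction)
    n_pairs = len(pairwise) * (len(pairwise) - 1) // 2
    xa_plain = x_vs_autosomes_test(table, "density")
    xa_corr = x_vs_autosomes_test(table, "density", n_comparisons=n_pairs)
    ratio = float(np.mean(table.x_values("density"))
                  / np.mean(table.autosomal_values("density")))
    return DensityByChromosome(summaries, xa_plain, xa_corr, pairwise, ratio)
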