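"""Per-chromosome descriptive statistics and nonparametric tests.

The central comparison throughout is the X chromosome against the pooled
autosomes ("A"): arithmetic means/medians with 95% confidence intervals per
chromosome, Kruskal-Wallis omnibus and pairwise tests with multiple-testing
correction, per-compartment Spearman correlations, housekeeping
stratification, and paired control/treatment deltas.

The pooled "A" row weights every autosomal gene equally (it is not an
average of chromosome averages); a chromosome-weighted mean is reported
alongside for reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError
from .tables import GeneTable

__all__ = [
    "ChromosomeSummary",
    "TestResult",
    "chromosome_summary",
    "summaries_to_frame",
    "kruskal_wallis",
    "pairwise_chromosome_tests",
    "x_vs_autosomes_test",
    "spearman_by_group",
    "stratify_housekeeping",
    "paired_condition_delta",
    "xaa_ratio",
]

logger = logging.getLogger(__name__)

_CORRECTIONS = {"bonferroni": "bonferroni", "holm": "holm"}


@dataclass(frozen=True)
class ChromosomeSummary:
    chromosome: str
    n: int
    mean: float
    median: float
    ci_low: float
    ci_high: float
    value_name: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    method: str
    corrected: bool = False
    n_comparisons: int = 1


def _mean_ci(values: np.ndarray, method: str = "t", n_boot: int = 2000,
             rng: np.random.Generator | None = None) -> tuple[float, float]:
    """95% CI of the mean. Student-t by default; bootstrap percentile as an
    alternative. A single observation gets a degenerate interval."""
    n = len(values)
    m = float(np.mean(values))
    if n < 2 or float(np.std(values)) == 0.0:
        return m, m
    if method == "t":
        half = sps.t.ppf(0.975, n - 1) * sps.sem(values)
        return m - half, m + half
    if method == "bootstrap":
        rng = rng if rng is not None else np.random.default_rng(0)
        idx = rng.integers(0, n, size=(n_boot, n))
        means = values[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return float(lo), float(hi)
    raise ConfigurationError(f"unknown CI method {method!r}")


def _summarize(values: np.ndarray, label: str, value_name: str,
               ci_method: str = "t", rng=None) -> ChromosomeSummary:
    lo, hi = _mean_ci(values, ci_method, rng=rng)
    return ChromosomeSummary(
        chromosome=label, n=len(values), mean=float(np.mean(values)),
        median=float(np.median(values)), ci_low=lo, ci_high=hi,
        value_name=value_name,
    )


def chromosome_summary(
    table: GeneTable,
    value_name: str = "half_life_h",
    ci_method: str = "t",
    exclude_capped: bool = False,
    rng: np.random.Generator | None = None,
) -> list[ChromosomeSummary]:
    """Mean/median/95% CI per chromosome plus the pooled-autosome "A" row.

    Chromosomes with no data are omitted (never zero-filled). The X row is
    its own chromosome row, listed after "A".
    """
    karyo = table.karyotype
    out: list[ChromosomeSummary] = []
    any_values = False
    for chrom in karyo.autosomes:
        vals = table.values_for(value_name, [chrom], exclude_capped=exclude_capped)
        if len(vals) == 0:
            continue
        any_values = True
        out.append(_summarize(vals, chrom, value_name, ci_method, rng))
    auto = table.autosomal_values(value_name, exclude_capped=exclude_capped)
    if len(auto):
        out.append(_summarize(auto, "A", value_name, ci_method, rng))
    for chrom in karyo.sex_chromosomes:
        vals = table.values_for(value_name, [chrom], exclude_capped=exclude_capped)
        if len(vals) == 0:
            continue
        any_values = True
        out.append(_summarize(vals, chrom, value_name, ci_method, rng))
    if not any_values:
        raise InputError(f"no values present for {value_name!r}")
    return out


def summaries_to_frame(summaries: Sequence[ChromosomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square, k-1 df."""
    if len(groups) < 2:
        raise InputError("kruskal_wallis needs at least 2 groups")
    arrays = []
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) == 0:
            raise InputError(f"group {name!r} has no non-missing values")
        arrays.append(arr)
    if sum(map(len, arrays)) < 3:
        raise InputError("kruskal_wallis needs at least 3 observations in total")
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = sps.kruskal(*arrays)
    except ValueError:
        # all observations identical: no evidence of any difference
        stat, p = 0.0, 1.0
    if np.isnan(stat):
        stat, p = 0.0, 1.0
    return TestResult(float(stat), float(p), tuple(groups), "kruskal-wallis")


def pairwise_chromosome_tests(
    table: GeneTable,
    value_name: str = "half_life_h",
    correction: str = "bonferroni",
    exclude_capped: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis on every unordered chromosome pair, corrected over the
    full pair count. Returns a symmetric matrix with unit diagonal."""
    if correction not in _CORRECTIONS:
        raise ConfigurationError(f"unknown correction {correction!r}")
    chroms = [
        c for c in table.karyotype.names
        if len(table.values_for(value_name, [c], exclude_capped=exclude_capped))
    ]
    if len(chroms) < 2:
        raise InputError("need data on at least 2 chromosomes")
    values = {
        c: table.values_for(value_name, [c], exclude_capped=exclude_capped)
        for c in chroms
    }
    pairs = list(itertools.combinations(chroms, 2))
    raw = [
        kruskal_wallis({a: values[a], b: values[b]}).p_value for a, b in pairs
    ]
    corrected = multipletests(raw, method=_CORRECTIONS[correction])[1]
    mat = pd.DataFrame(np.ones((len(chroms), len(chroms))), index=chroms,
                       columns=chroms)
    for (a, b), p in zip(pairs, corrected):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def x_vs_autosomes_test(
    table: GeneTable,
    value_name: str = "half_life_h",
    n_comparisons: int | None = None,
    exclude_capped: bool = False,
) -> TestResult:
    """Kruskal-Wallis of X values against the pooled autosomal values.

    With ``n_comparisons`` set, the p-value is Bonferroni-scaled by that
    count so the single X-vs-A test can be reported on the same footing as
    the pairwise family it accompanies.
    """
    x = table.x_values(value_name, exclude_capped=exclude_capped)
    a = table.autosomal_values(value_name, exclude_capped=exclude_capped)
    if len(x) == 0 or len(a) == 0:
        raise InputError("both X and autosomal values are required")
    res = kruskal_wallis({"X": x, "A": a})
    if n_comparisons is None:
        return res
    return TestResult(
        res.statistic, min(1.0, res.p_value * n_comparisons), res.groups,
        res.method, corrected=True, n_comparisons=n_comparisons,
    )


def spearman_by_group(
    table: GeneTable, x_name: str, y_name: str
) -> dict[str, float | None]:
    """Spearman rho of two gene-level columns, separately for the X
    chromosome and the pooled autosomes. Undefined (constant-input)
    correlations are reported as ``None``, never 0."""
    out: dict[str, float | None] = {}
    for label, chroms in (
        ("X", table.karyotype.sex_chromosomes),
        ("A", table.karyotype.autosomes),
    ):
        sub = table.df[
            table.df["chromosome"].isin(list(chroms))
            & table.df[x_name].notna()
            & table.df[y_name].notna()
        ]
        if len(sub) < 3:
            raise InputError(f"fewer than 3 paired observations in group {label}")
        x = sub[x_name].to_numpy(dtype=float)
        y = sub[y_name].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[label] = None
            continue
        rho = sps.spearmanr(x, y).statistic
        out[label] = float(rho)
    return out


@dataclass(frozen=True)
class StratifiedResult:
    """2x2 housekeeping stratification: summaries per (compartment, flag)
    cell plus the housekeeping:non-housekeeping gene-count ratio per
    compartment (``None`` when undefined)."""

    cells: dict[tuple[str, bool], ChromosomeSummary]
    count_ratio: dict[str, float | None]
    n_flag_missing: int


def stratify_housekeeping(
    table: GeneTable, value_name: str = "half_life_h"
) -> StratifiedResult:
    df = table.df[table.df[value_name].notna()]
    missing = int(df["is_housekeeping"].isna().sum())
    if missing:
        logger.info("stratify_housekeeping: %d gene(s) lack the flag; excluded",
                    missing)
    df = df[df["is_housekeeping"].notna()]
    if df.empty:
        raise InputError("no genes with both value and housekeeping flag")
    is_auto = df["chromosome"].isin(list(table.karyotype.autosomes))
    cells: dict[tuple[str, bool], ChromosomeSummary] = {}
    ratio: dict[str, float | None] = {}
    for label, mask in (("A", is_auto), ("X", ~is_auto)):
        n_by_flag = {}
        for flag in (True, False):
            vals = df.loc[mask & (df["is_housekeeping"] == flag),
                          value_name].to_numpy(dtype=float)
            n_by_flag[flag] = len(vals)
            if len(vals):
                cells[(label, flag)] = _summarize(vals, label, value_name)
        ratio[label] = (
            n_by_flag[True] / n_by_flag[False] if n_by_flag[False] else None
        )
    return StratifiedResult(cells=cells, count_ratio=ratio,
                            n_flag_missing=missing)


def paired_condition_delta(
    pair: pd.DataFrame, table: GeneTable
) -> pd.DataFrame:
    """Per-chromosome means of paired half-lives and their difference.

    ``pair`` must carry gene_id/control/treatment; only genes measured under
    both conditions (and present in the table) are used. Returns one row per
    chromosome plus pooled "A" and "X" rows with columns n, mean_control,
    mean_treatment, mean_delta (treatment - control).
    """
    need = {"gene_id", "control", "treatment"}
    if not need.issubset(pair.columns):
        raise InputError(f"pair table must have columns {sorted(need)}")
    merged = pair.dropna(subset=["control", "treatment"]).merge(
        table.df[["gene_id", "chromosome"]], on="gene_id", how="inner"
    )
    if merged.empty:
        raise InputError("no genes paired under both conditions")
    merged["delta"] = merged["treatment"] - merged["control"]

    def _row(label: str, sub: pd.DataFrame) -> dict:
        return {
            "chromosome": label,
            "n": len(sub),
            "mean_control": sub["control"].mean(),
            "mean_treatment": sub["treatment"].mean(),
            "mean_delta": sub["delta"].mean(),
        }

    karyo = table.karyotype
    rows = []
    for chrom in karyo.names:
        sub = merged[merged["chromosome"] == chrom]
        if len(sub):
            rows.append(_row(chrom, sub))
    auto = merged[merged["chromosome"].isin(list(karyo.autosomes))]
    if len(auto):
        rows.append(_row("A", auto))
    return pd.DataFrame(rows)


def xaa_ratio(table: GeneTable, value_name: str = "half_life_h",
              exclude_capped: bool = False) -> float:
    """X-chromosome mean divided by the pooled autosomal mean (X:AA)."""
    x = table.x_values(value_name, exclude_capped=exclude_capped)
    a = table.autosomal_values(value_name, exclude_capped=exclude_capped)
    if len(x) == 0 or len(a) == 0:
        raise InputError("both compartments must be non-empty")
    a_mean = float(np.mean(a))
    if a_mean == 0:
        raise InputError("autosomal mean is zero; ratio undefined")
    return float(np.mean(x)) / a_mean
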