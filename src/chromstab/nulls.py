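"""Resampling empirical null for the X-chromosome mean, and spatial
sliding-window profiles along chromosome arms.

The null asks: if the X chromosome were an arbitrary subset of autosomal
genes, how often would a random set of the same size reach the observed X
mean? Samples are drawn without replacement within a sample and
independently (with replacement) across samples. The empirical p uses the
add-one convention (count_ge + 1)/(B + 1) so it is never exactly zero, and
ties at the observed value count as exceedances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GeneLookupError, InputError
from .tables import GeneTable

__all__ = [
    "ResamplingResult",
    "WindowProfile",
    "Window",
    "resample_null",
    "sample_means",
    "sliding_window_profile",
    "locate_gene_window",
]

logger = logging.getLogger(__name__)

try:  # numba accelerates the inner Floyd loop; the fallback is identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _floyd_means_py(values, n_draw, uniforms, out):
    n_pop = values.shape[0]
    n_b = uniforms.shape[0]
    chosen = np.zeros(n_pop, dtype=np.bool_)
    picks = np.empty(n_draw, dtype=np.int64)
    for b in range(n_b):
        s = 0.0
        for i in range(n_draw):
            j = n_pop - n_draw + i
            t = int(uniforms[b, i] * (j + 1))
            if t > j:
                t = j
            idx = j if chosen[t] else t
            chosen[idx] = True
            picks[i] = idx
            s += values[idx]
        out[b] = s / n_draw
        for i in range(n_draw):
            chosen[picks[i]] = False
    return out


if _HAVE_NUMBA:
    _floyd_means_fast = _njit(cache=True)(_floyd_means_py)
else:  # pragma: no cover
    _floyd_means_fast = _floyd_means_py


def sample_means(
    values: np.ndarray,
    n_draw: int,
    n_samples: int,
    rng: np.random.Generator,
    chunk: int = 16_384,
) -> np.ndarray:
    """Means of ``n_samples`` subsets of size ``n_draw`` drawn without
    replacement (Floyd's algorithm, uniform over subsets), vectorised in
    chunks so B = 10^6 stays in bounded memory."""
    values = np.asarray(values, dtype=np.float64)
    if n_draw > len(values):
        raise InputError(
            f"n_draw={n_draw} exceeds population size {len(values)}"
        )
    if n_draw < 1 or n_samples < 1:
        raise InputError("n_draw and the number of samples must be >= 1")
    out = np.empty(n_samples, dtype=np.float64)
    done = 0
    while done < n_samples:
        b = min(chunk, n_samples - done)
        uniforms = rng.random((b, n_draw))
        _floyd_means_fast(values, n_draw, uniforms, out[done : done + b])
        done += b
    return out


@dataclass
class ResamplingResult:
    """Empirical null of autosome-sample means against the observed X mean."""

    n_draw: int
    B: int
    observed: float
    count_ge: int
    empirical_p: float
    seed: int
    hist_edges: np.ndarray = field(repr=False)
    hist_counts: np.ndarray = field(repr=False)
    sample_means: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_draw": self.n_draw,
            "B": self.B,
            "observed": self.observed,
            "count_ge": self.count_ge,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "hist_edges": [float(x) for x in self.hist_edges],
            "hist_counts": [int(x) for x in self.hist_counts],
        }


def resample_null(
    autosomal_values: Sequence[float],
    n_draw: int,
    B: int,
    observed: float,
    seed: int,
    keep_stream: bool = False,
) -> ResamplingResult:
    """Build the empirical null distribution of autosome-sample means.

    Draws ``B`` samples of ``n_draw`` autosomal values without replacement
    (independently across samples), counts how many sample means reach the
    observed X mean (>=, ties included), and reports the add-one empirical
    p. The raw exceedance count is kept because "none of B samplings
    reached the observed value" is itself the reportable outcome.
    """
    values = np.asarray(autosomal_values, dtype=float)
    values = values[~np.isnan(values)]
    if B < 1:
        raise InputError("B must be >= 1")
    rng = np.random.default_rng(seed)
    means = sample_means(values, n_draw, B, rng)
    count_ge = int(np.count_nonzero(means >= observed))
    # Freedman-Diaconis binning; degenerate streams collapse to one bin
    if np.ptp(means) == 0.0:
        edges = np.array([means[0] - 0.5, means[0] + 0.5])
        counts = np.array([B])
    else:
        counts, edges = np.histogram(means, bins="fd")
    return ResamplingResult(
        n_draw=n_draw, B=B, observed=float(observed), count_ge=count_ge,
        empirical_p=(count_ge + 1) / (B + 1), seed=seed,
        hist_edges=edges, hist_counts=counts,
        sample_means=means if keep_stream else None,
    )


@dataclass(frozen=True)
class Window:
    index: int
    mean: float
    gene_ids: tuple[str, ...]


@dataclass
class WindowProfile:
    """Sliding-window means of one chromosome arm, genes in coordinate
    order. ``gene_order`` is the full ordered gene list of the arm."""

    chromosome: str
    arm: str  # "p" or "q"
    window_size: int
    step: int
    windows: list[Window]
    gene_order: tuple[str, ...]


def sliding_window_profile(
    table: GeneTable,
    value_name: str = "half_life_h",
    window_size: int = 30,
    step: int = 1,
    arm_boundaries: Mapping[str, int] | None = None,
) -> list[WindowProfile]:
    """Windowed means along each chromosome arm.

    Genes (with the value present) are ordered by start coordinate within
    each arm (p: start < centromere coordinate; q: the rest); a window of
    ``window_size`` genes advances ``step`` genes at a time, giving
    max(0, n_arm - window_size + 1) windows per arm for step 1. Arms with
    fewer genes than one window yield an empty window list (logged).
    """
    if arm_boundaries is None:
        raise InputError("arm_boundaries (chromosome -> centromere bp) required")
    df = table.df[table.df[value_name].notna() & table.df["start"].notna()]
    profiles: list[WindowProfile] = []
    for chrom in table.karyotype.names:
        sub = df[df["chromosome"] == chrom]
        if sub.empty:
            continue
        if chrom not in arm_boundaries:
            raise InputError(f"no arm boundary provided for chromosome {chrom}")
        cen = arm_boundaries[chrom]
        for arm, arm_df in (("p", sub[sub["start"] < cen]),
                            ("q", sub[sub["start"] >= cen])):
            arm_df = arm_df.sort_values("start", kind="mergesort")
            vals = arm_df[value_name].to_numpy(dtype=float)
            ids = tuple(arm_df["gene_id"])
            n = len(vals)
            windows: list[Window] = []
            if n < window_size:
                logger.info("arm %s%s has %d genes < window %d; empty profile",
                            chrom, arm, n, window_size)
            else:
                csum = np.concatenate([[0.0], np.cumsum(vals)])
                for w_idx, i in enumerate(range(0, n - window_size + 1, step)):
                    mean = (csum[i + window_size] - csum[i]) / window_size
                    windows.append(Window(w_idx, float(mean),
                                          ids[i : i + window_size]))
            profiles.append(WindowProfile(chrom, arm, window_size, step,
                                          windows, ids))
    return profiles


@dataclass(frozen=True)
class LocatedWindow:
    chromosome: str
    arm: str
    window_index: int
    at_edge: bool


def locate_gene_window(
    profiles: Sequence[WindowProfile], gene_id: str
) -> LocatedWindow:
    """Find the window whose central member (position ceil(w/2) in
    coordinate order) is the query gene.

    Near an arm end no window is centred on the gene; the nearest window is
    returned with ``at_edge=True``.
    """
    for prof in profiles:
        if gene_id not in prof.gene_order:
            continue
        if not prof.windows:
            raise GeneLookupError(
                f"gene {gene_id!r} lies on arm {prof.chromosome}{prof.arm} "
                "with no windows"
            )
        rank = prof.gene_order.index(gene_id)
        centre_offset = -(-prof.window_size // 2) - 1  # ceil(w/2), 0-based
        ideal = (rank - centre_offset) / prof.step
        idx = int(round(ideal))
        n_win = len(prof.windows)
        clamped = min(max(idx, 0), n_win - 1)
        at_edge = clamped != ideal
        return LocatedWindow(prof.chromosome, prof.arm, clamped, at_edge)
    raise GeneLookupError(f"gene {gene_id!r} not present in any profile")
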