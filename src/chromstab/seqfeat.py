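"""Sequence-composition analyses: GC/GC3 of coding sequences, the 1..6-mer
3'-UTR word-frequency matrix with unit-variance-scaled PCA, and poly(A)
tail-length merging.

CDS are validated before GC statistics: anything shorter than 60 nt or not
starting with ATG is discarded (a 60 nt CDS is kept — "shorter than" is read
strictly). Words are counted with overlap, never across sequence boundaries,
and windows containing N are skipped; each word count is divided by the
total sequence length of the chromosome's UTR set.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import InputError
from .stats import ChromosomeSummary, chromosome_summary
from .tables import GeneTable, SeqRecord

__all__ = [
    "CdsValidity",
    "KmerMatrix",
    "PcaResult",
    "gc_content",
    "gc3_content",
    "filter_cds",
    "gc_by_chromosome",
    "kmer_word_matrix",
    "all_words",
    "uv_scale_pca",
    "merge_polya",
    "PolyaResult",
]

logger = logging.getLogger(__name__)

MIN_CDS_LENGTH = 60
START_CODON = "ATG"


def gc_content(seq: str) -> float | None:
    """(G+C)/(A+C+G+T); N excluded from both sides; ``None`` if all-N."""
    if not seq:
        raise InputError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return gc / acgt


def gc3_content(cds: str) -> float | None:
    """GC fraction of codon third (wobble) positions; N positions excluded.

    A trailing partial codon is ignored with a warning.
    """
    if len(cds) < 3:
        raise InputError("no complete codon in sequence")
    if len(cds) % 3:
        warnings.warn("trailing partial codon ignored", stacklevel=2)
    seq = cds.upper()
    thirds = seq[2 : 3 * (len(seq) // 3) : 3]
    counted = [b for b in thirds if b in "ACGT"]
    if not counted:
        return None
    return sum(b in "GC" for b in counted) / len(counted)


@dataclass(frozen=True)
class CdsValidity:
    record: SeqRecord
    is_valid: bool
    reject_reason: str | None  # "too_short" | "no_start_codon" | None


def filter_cds(
    records: Sequence[SeqRecord],
) -> tuple[list[CdsValidity], list[CdsValidity]]:
    """Split CDS into valid (>= 60 nt and starting ATG) and rejected, the
    reject carrying the first applicable reason (too_short before
    no_start_codon)."""
    valid: list[CdsValidity] = []
    rejected: list[CdsValidity] = []
    for rec in records:
        if len(rec.sequence) < MIN_CDS_LENGTH:
            rejected.append(CdsValidity(rec, False, "too_short"))
        elif not rec.sequence.startswith(START_CODON):
            rejected.append(CdsValidity(rec, False, "no_start_codon"))
        else:
            valid.append(CdsValidity(rec, True, None))
    return valid, rejected


def gc_by_chromosome(valid: Sequence[CdsValidity]) -> pd.DataFrame:
    """Mean GC and GC3 of validated CDS per chromosome, with the CDS count."""
    rows: dict[str, dict] = {}
    for v in valid:
        rec = v.record
        acc = rows.setdefault(rec.chromosome, {"n_cds": 0, "gc": [], "gc3": []})
        acc["n_cds"] += 1
        gc = gc_content(rec.sequence)
        g3 = gc3_content(rec.sequence)
        if gc is not None:
            acc["gc"].append(gc)
        if g3 is not None:
            acc["gc3"].append(g3)
    if not rows:
        raise InputError("no valid CDS")
    return pd.DataFrame(
        [
            {
                "chromosome": chrom,
                "n_cds": acc["n_cds"],
                "mean_gc": float(np.mean(acc["gc"])) if acc["gc"] else np.nan,
                "mean_gc3": float(np.mean(acc["gc3"])) if acc["gc3"] else np.nan,
            }
            for chrom, acc in rows.items()
        ]
    )


# ---------------------------------------------------------------------------
# k-mer word matrix


def all_words(k_max: int = 6) -> list[str]:
    """All DNA words of lengths 1..k_max in lexicographic order per length."""
    words: list[str] = []
    for k in range(1, k_max + 1):
        words.extend("".join(p) for p in itertools.product("ACGT", repeat=k))
    return words


_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _count_words(seqs: Sequence[str], k_max: int) -> tuple[list[np.ndarray], list[int]]:
    """Overlapping word counts per k (1..k_max) summed over sequences.

    Rolling base-4 codes with an N-validity mask; windows containing N are
    skipped and windows never span sequence boundaries.
    """
    counts = [np.zeros(4 ** k, dtype=np.int64) for k in range(1, k_max + 1)]
    n_windows = [0] * k_max
    for seq in seqs:
        enc = _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        code = enc.copy()
        valid = enc >= 0
        if valid.any():
            counts[0] += np.bincount(code[valid], minlength=4)
        n_windows[0] += int(valid.sum())
        for k in range(2, k_max + 1):
            if len(code) < 2:
                break
            code = code[:-1] * 4 + enc[k - 1 :]
            valid = valid[:-1] & (enc[k - 1 :] >= 0)
            if valid.any():
                counts[k - 1] += np.bincount(code[valid], minlength=4 ** k)
            n_windows[k - 1] += int(valid.sum())
    return counts, n_windows


@dataclass
class KmerMatrix:
    """Chromosomes x word frequencies (lengths 1..k_max, 5,460 columns for
    k_max=6). ``frame`` holds length-normalised counts, ``counts`` the raw
    overlapping-window counts."""

    frame: pd.DataFrame
    counts: pd.DataFrame = field(repr=False)
    k_max: int = 6
    total_length: dict[str, int] = field(default_factory=dict)


def kmer_word_matrix(
    utr_sequences_by_chromosome: Mapping[str, Sequence[SeqRecord]],
    k_max: int = 6,
    denominator: str = "length",
) -> KmerMatrix:
    """Count all words of length 1..k_max per chromosome over its 3'-UTR set.

    Each word's count is divided by the chromosome's total UTR sequence
    length (``denominator="length"``, the default) or by the number of
    usable windows for that word length (``denominator="windows"``).
    """
    if denominator not in ("length", "windows"):
        raise InputError(f"unknown denominator {denominator!r}")
    words = all_words(k_max)
    raw_rows, norm_rows, totals = {}, {}, {}
    for chrom, seqs in utr_sequences_by_chromosome.items():
        if not seqs or max(len(s.sequence) for s in seqs) < k_max:
            raise InputError(
                f"chromosome {chrom!r} has no sequence of length >= {k_max}"
            )
        counts, n_windows = _count_words([s.sequence for s in seqs], k_max)
        total_len = sum(len(s.sequence) for s in seqs)
        totals[chrom] = total_len
        for k in range(1, k_max + 1):
            if n_windows[k - 1] == 0:
                raise InputError(
                    f"chromosome {chrom!r} has zero usable windows for k={k}"
                )
        raw_rows[chrom] = np.concatenate(counts)
        if denominator == "length":
            norm_rows[chrom] = np.concatenate(
                [counts[k - 1] / total_len for k in range(1, k_max + 1)]
            )
        else:
            norm_rows[chrom] = np.concatenate(
                [counts[k - 1] / n_windows[k - 1] for k in range(1, k_max + 1)]
            )
    frame = pd.DataFrame.from_dict(norm_rows, orient="index", columns=words)
    counts_df = pd.DataFrame.from_dict(raw_rows, orient="index", columns=words)
    return KmerMatrix(frame=frame, counts=counts_df, k_max=k_max,
                      total_length=totals)


@dataclass
class PcaResult:
    """PCA of the unit-variance-scaled word matrix.

    ``explained_variance_pct`` is each component's share of the total
    variance; ``explained_remaining_pct`` is its share of the variance left
    after the preceding components (the "x% of total and y% of remaining"
    reporting convention).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame = field(repr=False)
    explained_variance_pct: list[float] = field(default_factory=list)
    explained_remaining_pct: list[float] = field(default_factory=list)
    r2_cumulative: float = 0.0
    n_dropped_columns: int = 0


def uv_scale_pca(
    matrix: KmerMatrix | pd.DataFrame,
    n_components: int = 2,
    center: bool = True,
) -> PcaResult:
    """Unit-variance scale each column (center, divide by sd; zero-variance
    columns dropped with a logged count), then PCA by SVD."""
    frame = matrix.frame if isinstance(matrix, KmerMatrix) else matrix
    if len(frame) < 2:
        raise InputError("PCA needs at least 2 rows")
    X = frame.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("uv_scale_pca: dropped %d zero-variance column(s)", n_dropped)
    X = X[:, keep]
    if X.shape[1] == 0:
        raise InputError("all columns have zero variance")
    mean = X.mean(axis=0) if center else 0.0
    Xs = (X - mean) / sd[keep]
    n_components = min(n_components, len(frame) - 1, Xs.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    # deterministic sign: largest-magnitude loading positive
    for j in range(n_components):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    frac = pca.explained_variance_ratio_
    remaining_pct = []
    left = 1.0
    for f in frac:
        # at full rank the last component takes all that is left
        remaining_pct.append(100.0 * f / left if left > 1e-12 else 100.0)
        left -= f
    return PcaResult(
        scores=pd.DataFrame(scores, index=frame.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=frame.columns[keep], columns=comp_names
        ),
        explained_variance_pct=[100.0 * f for f in frac],
        explained_remaining_pct=remaining_pct,
        r2_cumulative=float(frac.sum()),
        n_dropped_columns=n_dropped,
    )


# ---------------------------------------------------------------------------
# poly(A) tail lengths


@dataclass
class PolyaResult:
    merged: GeneTable
    summaries: list[ChromosomeSummary]
    spearman_rho: float | None
    n_discarded: int


def merge_polya(
    halflife_table: GeneTable, polya_table: pd.DataFrame
) -> PolyaResult:
    """Inner-join per-gene poly(A) tail lengths onto the half-life table.

    Entries missing either value are discarded (count reported). Returns
    per-chromosome mean tail length and the gene-level Spearman correlation
    between tail length and half-life.
    """
    if not {"gene_id", "polya_len"}.issubset(polya_table.columns):
        raise InputError("polya table must have columns gene_id, polya_len")
    df = halflife_table.df.merge(
        polya_table[["gene_id", "polya_len"]], on="gene_id", how="inner"
    )
    n_before = len(df)
    df = df[df["half_life_h"].notna() & df["polya_len"].notna()]
    n_discarded = n_before - len(df)
    if df.empty:
        raise InputError("no genes shared between half-life and poly(A) tables")
    merged = GeneTable(df, halflife_table.dataset_label, halflife_table.karyotype)
    summaries = chromosome_summary(merged, "polya_len")
    x = df["polya_len"].to_numpy(dtype=float)
    y = df["half_life_h"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        rho = None
    else:
        from scipy import stats as sps

        rho = float(sps.spearmanr(x, y).statistic)
    return PolyaResult(merged, summaries, rho, n_discarded)
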