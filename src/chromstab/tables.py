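"""Gene tables, sequences and interval files.

The universal currency of the package is the :class:`GeneTable`: one row per
gene carrying identifiers, chromosome assignment, coordinates and the
per-gene measurements (half-life in hours, RPKM, mRNA length, housekeeping
flag). Interval files use the BED convention on disk (0-based, half-open);
internal gene coordinates are 1-based inclusive, and the two converters in
this module are the only place the shift occurs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, InputError
from .karyotype import HUMAN, Karyotype, normalize_chromosome

__all__ = [
    "GeneRecord",
    "GeneTable",
    "IntervalRecord",
    "SeqRecord",
    "read_gene_table",
    "write_gene_table",
    "intersect_tables",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "extract_utr_sequences",
    "reverse_complement",
    "group_by_chromosome",
]

logger = logging.getLogger(__name__)

#: canonical column order of a gene table frame
GENE_COLUMNS = [
    "gene_id",
    "chromosome",
    "strand",
    "start",
    "end",
    "half_life_h",
    "rpkm",
    "mrna_length_bp",
    "is_housekeeping",
    "capped",
]

_NUMERIC_FIELDS = ("start", "end", "half_life_h", "rpkm", "mrna_length_bp")


@dataclass(frozen=True)
class GeneRecord:
    """One gene. Optional measurements are ``None`` when absent — absence is
    never encoded as zero."""

    gene_id: str
    chromosome: str
    strand: str = "unknown"
    start: int | None = None
    end: int | None = None
    half_life_h: float | None = None
    rpkm: float | None = None
    mrna_length_bp: int | None = None
    is_housekeeping: bool | None = None
    capped: bool = False


@dataclass
class GeneTable:
    """An ordered gene-level table bound to a karyotype.

    ``df`` holds one row per gene with the columns in :data:`GENE_COLUMNS`
    (missing measurements are NaN/NA). ``rejected`` carries rows the reader
    could not place on a declared chromosome.
    """

    df: pd.DataFrame
    dataset_label: str = ""
    karyotype: Karyotype = HUMAN
    rejected: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in GENE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[GENE_COLUMNS + [c for c in df.columns if c not in GENE_COLUMNS]]
        df = df.reset_index(drop=True)
        self.df = df
        self.validate()

    def validate(self) -> None:
        dup = self.df["gene_id"][self.df["gene_id"].duplicated()]
        if len(dup):
            raise InputError(
                "duplicate gene_id(s): " + ", ".join(sorted(set(dup.astype(str))))
            )
        present = set(self.df["chromosome"].dropna().astype(str))
        unknown = present - set(self.karyotype.names)
        if unknown:
            raise InputError(
                f"chromosome(s) outside declared karyotype: {sorted(unknown)}"
            )
        hl = pd.to_numeric(self.df["half_life_h"], errors="coerce")
        if (hl.dropna() < 0).any():
            raise InputError("negative half-life values present")
        se = self.df[["start", "end"]].apply(pd.to_numeric, errors="coerce")
        both = se.dropna()
        if (both["start"] > both["end"]).any():
            raise InputError("gene with start > end")

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()

    def values_for(self, value_name: str, chromosomes: Iterable[str] | None = None,
                   exclude_capped: bool = False) -> np.ndarray:
        """Non-missing values of one column, optionally restricted."""
        if value_name not in self.df.columns:
            raise InputError(f"unknown value column {value_name!r}")
        mask = self.df[value_name].notna()
        if chromosomes is not None:
            mask &= self.df["chromosome"].isin(list(chromosomes))
        if exclude_capped and "capped" in self.df.columns:
            mask &= ~self.df["capped"].fillna(False).astype(bool)
        return self.df.loc[mask, value_name].to_numpy(dtype=float)

    def autosomal_values(self, value_name: str, **kw) -> np.ndarray:
        return self.values_for(value_name, self.karyotype.autosomes, **kw)

    def x_values(self, value_name: str, **kw) -> np.ndarray:
        return self.values_for(value_name, self.karyotype.sex_chromosomes, **kw)

    def subset(self, gene_ids: Sequence[str]) -> "GeneTable":
        """Rows for ``gene_ids`` in the order given."""
        idx = self.df.set_index("gene_id").reindex(gene_ids)
        if idx["chromosome"].isna().any():
            missing = [g for g in gene_ids
                       if g not in set(self.df["gene_id"])]
            raise InputError(f"gene id(s) not in table: {missing[:5]}")
        return GeneTable(idx.reset_index(), self.dataset_label, self.karyotype)


# ---------------------------------------------------------------------------
# coordinate convention converters — the only place the 0/1-based shift occurs


def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """BED 0-based half-open -> internal 1-based inclusive."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Internal 1-based inclusive -> BED 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# gene-table I/O


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_gene_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    karyotype: Karyotype = HUMAN,
    dataset_label: str = "",
) -> GeneTable:
    """Read a TSV/CSV gene table.

    ``column_map`` maps semantic field names (keys of :data:`GENE_COLUMNS`)
    to source column names; identity mapping by default. Rows whose
    chromosome cannot be normalized onto the karyotype are placed on the
    table's ``rejected`` frame, not silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    raw = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    column_map = dict(column_map or {})
    for semantic in ("gene_id", "chromosome"):
        source = column_map.get(semantic, semantic)
        if source not in raw.columns:
            raise ConfigurationError(
                f"mandatory column {source!r} (for {semantic!r}) missing from {path}"
            )
    out = pd.DataFrame()
    for semantic in GENE_COLUMNS:
        source = column_map.get(semantic, semantic)
        if source in raw.columns:
            out[semantic] = raw[source]
    for col in _NUMERIC_FIELDS:
        if col in out.columns:
            try:
                # astype, not to_numeric: the latter's fast path is not
                # correctly rounded, which would break bit-exact round trips
                out[col] = out[col].astype("float64")
            except (ValueError, TypeError) as exc:
                raise InputError(f"column {col!r} not numeric in {path}: {exc}")
    if "is_housekeeping" in out.columns:
        out["is_housekeeping"] = out["is_housekeeping"].map(
            {"True": True, "False": False, "1": True, "0": False,
             True: True, False: False}
        )
    dup = out["gene_id"][out["gene_id"].duplicated()]
    if len(dup):
        raise InputError(
            "duplicate gene_id(s) in input: "
            + ", ".join(sorted(set(dup.astype(str))))
        )
    norm = out["chromosome"].map(lambda c: normalize_chromosome(c) if pd.notna(c) else None)
    ok = norm.notna() & norm.isin(list(karyotype.names))
    rejected = out[~ok].copy()
    if len(rejected):
        logger.info("read_gene_table: %d row(s) rejected (unplaceable chromosome)",
                    len(rejected))
    out = out[ok].copy()
    out["chromosome"] = norm[ok]
    table = GeneTable(out, dataset_label=dataset_label, karyotype=karyotype)
    table.rejected = rejected
    return table


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    """Write a gene table as TSV with a commented provenance header."""
    from . import __version__

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dataset_label={table.dataset_label}\tchromstab={__version__}\n")
        table.df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def intersect_tables(tables: Sequence[GeneTable]) -> list[GeneTable]:
    """Restrict every table to the genes with a half-life in all tables.

    The shared genes keep the order they have in the first table, and that
    order is used for every output so the tables align row-by-row.
    """
    if len(tables) < 2:
        raise InputError("intersect_tables needs at least 2 tables")
    sets = []
    for t in tables:
        sets.append(set(t.df.loc[t.df["half_life_h"].notna(), "gene_id"]))
    common = set.intersection(*sets)
    if not common:
        warnings.warn("intersect_tables: empty gene intersection", stacklevel=2)
    first = tables[0]
    order = [g for g in first.df["gene_id"] if g in common]
    return [t.subset(order) for t in tables]


# ---------------------------------------------------------------------------
# sequences and intervals


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N} (uppercase canonical)."""

    id: str
    sequence: str
    chromosome: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IntervalRecord:
    """A BED-style interval: 0-based half-open, stranded."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")


_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file to uppercase records; reject non-DNA characters."""
    path = Path(path)
    records: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            raise InputError(
                f"record {rec.id!r} contains non-DNA characters {sorted(bad)}"
            )
        if not seq:
            raise InputError(f"record {rec.id!r} has an empty sequence")
        records.append(SeqRecord(id=rec.id, sequence=seq, chromosome=rec.id))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[IntervalRecord]:
    """Read BED intervals (strand from column 6 when present, else '+')."""
    intervals: list[IntervalRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            intervals.append(IntervalRecord(chrom, start, end, strand, name))
    return intervals


def write_bed(intervals: Iterable[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


def extract_utr_sequences(
    intervals: Sequence[IntervalRecord],
    genome: Mapping[str, SeqRecord],
) -> list[SeqRecord]:
    """Slice interval sequences out of chromosome sequences.

    Minus-strand intervals are reverse-complemented so the returned sequence
    reads in the sense orientation of the transcript. Output ids carry the
    source interval name.
    """
    out: list[SeqRecord] = []
    for iv in intervals:
        if iv.chromosome not in genome:
            raise InputError(f"chromosome {iv.chromosome!r} absent from genome")
        chrom_seq = genome[iv.chromosome].sequence
        if iv.end > len(chrom_seq):
            raise InputError(
                f"interval {iv.chromosome}:{iv.start}-{iv.end} beyond chromosome "
                f"end ({len(chrom_seq)} bp)"
            )
        seq = chrom_seq[iv.start : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        out.append(SeqRecord(id=iv.name or f"{iv.chromosome}:{iv.start}-{iv.end}",
                             sequence=seq, chromosome=iv.chromosome))
    return out


def group_by_chromosome(records: Iterable[SeqRecord]) -> dict[str, list[SeqRecord]]:
    """Bucket sequence records by their chromosome attribute."""
    groups: dict[str, list[SeqRecord]] = {}
    for rec in records:
        groups.setdefault(rec.chromosome, []).append(rec)
    return groups
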