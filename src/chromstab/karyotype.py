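"""Karyotype declarations and chromosome-name normalization.

Analyses in this package compare the X chromosome against the pooled
autosomes, so every :class:`~chromstab.tables.GeneTable` carries an explicit
karyotype stating which chromosome names exist and which of them are
autosomes. Mitochondrial and unplaced contigs are outside the analysis and
are dropped at ingestion time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Karyotype", "HUMAN", "MOUSE", "normalize_chromosome"]


@dataclass(frozen=True)
class Karyotype:
    """Named chromosomes of a dataset, tagged autosome vs sex chromosome."""

    autosomes: tuple[str, ...]
    sex_chromosomes: tuple[str, ...] = ("X",)
    name: str = ""

    @property
    def names(self) -> tuple[str, ...]:
        return self.autosomes + self.sex_chromosomes

    def is_autosome(self, chromosome: str) -> bool:
        return chromosome in self.autosomes

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.names


HUMAN = Karyotype(tuple(str(i) for i in range(1, 23)), ("X",), name="human")
MOUSE = Karyotype(tuple(str(i) for i in range(1, 20)), ("X",), name="mouse")

# Names that denote sequence outside the autosome+X analysis universe.
_DROP = re.compile(r"^(M|MT)$|un|random|alt|fix|hap|scaffold|contig", re.IGNORECASE)


def normalize_chromosome(raw: str) -> str | None:
    """Normalize a chromosome label; return ``None`` for dropped contigs.

    Strips a leading ``chr`` prefix and uppercases X/Y. Mitochondrial and
    unplaced/alternate contigs map to ``None`` (the caller logs the count).
    """
    name = str(raw).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name or _DROP.search(name):
        return None
    if name.upper() in ("X", "Y"):
        return name.upper()
    return name
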