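"""Core domain types: alignments, nucleotide sequences, lineage tables.

Coordinates are 0-based, half-open throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"
AA_SET = frozenset(AA_LETTERS)
ALN_SET = AA_SET | {"-", "X"}
NUC_SET = frozenset("ACGTN")

CLADES = ("A", "B", "C", "D", "unknown")


class RadsigError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class NucSequence:
    """A nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise RadsigError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - NUC_SET
        if bad:
            raise RadsigError(
                f"sequence {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinAlignment:
    """Fixed-length aligned amino-acid sequences.

    Rows are equal-length strings over the 20 amino-acid letters plus
    ``-`` (gap) and ``X`` (unknown residue).
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise RadsigError("ids and rows differ in number")
        if not self.rows:
            raise RadsigError("alignment has no sequences")
        self.rows = [r.upper() for r in self.rows]
        length = len(self.rows[0])
        if length < 1:
            raise RadsigError("alignment has zero columns")
        for i, r in enumerate(self.rows):
            if len(r) != length:
                raise RadsigError(
                    f"row {self.ids[i]!r} has length {len(r)}, expected {length}"
                )
            bad = set(r) - ALN_SET
            if bad:
                raise RadsigError(
                    f"row {self.ids[i]!r} contains invalid characters: {sorted(bad)}"
                )
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise RadsigError(f"duplicate sequence id {sid!r}")
            seen.add(sid)

    @property
    def length(self) -> int:
        """Number of columns (amino-acid positions)."""
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise RadsigError(f"no sequence with id {sid!r}") from None

    def subset(self, ids: list[str]) -> "ProteinAlignment":
        return ProteinAlignment(list(ids), [self.row(i) for i in ids])

    def columns(self, indices: list[int]) -> "ProteinAlignment":
        rows = ["".join(r[j] for j in indices) for r in self.rows]
        return ProteinAlignment(list(self.ids), rows)


@dataclass
class GapFilterResult:
    alignment: ProteinAlignment
    kept_columns: list[int]


def gap_fraction_filter(aln: ProteinAlignment, max_gap: float) -> GapFilterResult:
    """Drop alignment columns whose gap fraction exceeds ``max_gap``.

    Column order is preserved; the indices of the kept columns (on the
    input alignment) are reported alongside the filtered alignment.
    """
    if not 0.0 <= max_gap <= 1.0:
        raise RadsigError(f"max_gap must be in [0, 1], got {max_gap}")
    n = aln.n_sequences
    kept = []
    for j in range(aln.length):
        gaps = sum(1 for r in aln.rows if r[j] == "-")
        if gaps / n <= max_gap:
            kept.append(j)
    if not kept:
        raise RadsigError("gap filter removed every column")
    return GapFilterResult(aln.columns(kept), kept)


@dataclass
class LineageTable:
    """Lineage metadata: one record per element lineage.

    Each record carries the lineage identifier (matching a tree leaf
    label when used with a tree), the host species, and the element
    clade (A-D or unknown).
    """

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lid, _species, clade in self.records:
            if lid in seen:
                raise RadsigError(f"duplicate lineage_id {lid!r}")
            seen.add(lid)
            if clade not in CLADES:
                raise RadsigError(
                    f"lineage {lid!r} has invalid clade {clade!r}; expected one of {CLADES}"
                )

    @property
    def lineage_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def species_of(self) -> dict[str, str]:
        return {lid: sp for lid, sp, _ in self.records}

    def clade_of(self) -> dict[str, str]:
        return {lid: cl for lid, _, cl in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["lineage_id", "species", "clade"])
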