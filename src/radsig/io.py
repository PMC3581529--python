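"""Readers and writers for FASTA sequences/alignments and lineage tables."""
from __future__ import annotations

from Bio import SeqIO

from .core import LineageTable, NucSequence, ProteinAlignment, RadsigError


def _read_fasta_records(path) -> list[tuple[str, str]]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise RadsigError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise RadsigError(f"empty record {rec.id!r} in {path}")
        records.append((rec.id, seq))
    if not records:
        raise RadsigError(f"no FASTA records in {path}")
    return records


def read_fasta_nuc(path) -> list[NucSequence]:
    return [NucSequence(i, s) for i, s in _read_fasta_records(path)]


def read_fasta_alignment(path) -> ProteinAlignment:
    recs = _read_fasta_records(path)
    return ProteinAlignment([i for i, _ in recs], [s for _, s in recs])


def write_fasta(records, path, width: int = 60) -> None:
    """Write NucSequence records or a ProteinAlignment as FASTA."""
    if isinstance(records, ProteinAlignment):
        items = zip(records.ids, records.rows)
    else:
        items = ((r.id, r.seq) for r in records)
    with open(path, "w") as fh:
        for sid, seq in items:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_lineage_table(path) -> LineageTable:
    """Tab-separated table with header lineage_id/species/clade."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise RadsigError(f"empty lineage table {path}")
    header = lines[0].split("\t")
    if header[:3] != ["lineage_id", "species", "clade"]:
        raise RadsigError(
            "lineage table must start with header lineage_id<TAB>species<TAB>clade"
        )
    records = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < 3:
            raise RadsigError(f"malformed lineage table row: {ln!r}")
        records.append((parts[0], parts[1], parts[2]))
    return LineageTable(records)


def write_lineage_table(table: LineageTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("lineage_id\tspecies\tclade\n")
        for lid, sp, cl in table.records:
            fh.write(f"{lid}\t{sp}\t{cl}\n")
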