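"""FASTA and alignment I/O helpers (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_sequences", "write_sequences", "ungap", "column_map"]


def read_sequences(path: str | Path, strip_gaps: bool = False) -> dict[str, str]:
    """Read a (possibly aligned) multi-FASTA into an ordered ``{id: seq}`` map.

    Sequences are uppercased; ``-`` gap characters are preserved unless
    ``strip_gaps`` is set. Duplicate ids and empty files are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if strip_gaps:
            seq = seq.replace("-", "")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_sequences(path: str | Path, records: dict[str, str]) -> None:
    """Write ``{id: seq}`` to FASTA, preserving order."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def ungap(seq: str) -> str:
    return seq.replace("-", "")


def column_map(aligned: str) -> list[int]:
    """Map ungapped residue index -> alignment column for one aligned row."""
    return [col for col, ch in enumerate(aligned) if ch != "-"]
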