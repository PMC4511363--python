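"""FASTA input/output (thin wrapper over Bio.SeqIO).

Identifiers preserve the full description line, since design reports refer
back to background proteins by whatever the source database called them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file as ``[(description, sequence), ...]``."""
    return [
        (rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(identifier, sequence)`` pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=ident.split()[0], description=ident)
        for ident, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
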