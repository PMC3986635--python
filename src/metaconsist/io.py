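"""Shared FASTA and table I/O."""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = ["FastaRecord", "FastaFormatError", "read_fasta", "write_fasta",
           "read_truth_table"]

_STANDARD = set("ACGT")


class FastaFormatError(ValueError):
    pass


@dataclass
class FastaRecord:
    id: str
    sequence: str
    #: True when the record contained characters outside A/C/G/T (kept as-is,
    #: uppercased).
    nonstandard: bool = False


def read_fasta(stream: IO[str]) -> list[FastaRecord]:
    """Parse FASTA (wrapped or unwrapped); sequences are uppercased and
    non-ACGT characters preserved but flagged.  Empty sequences are errors.
    """
    records = []
    for title, seq in SimpleFastaParser(stream):
        rid = title.split()[0] if title.split() else title
        seq = seq.upper()
        if not seq:
            raise FastaFormatError(f"record {rid!r} has an empty sequence")
        records.append(FastaRecord(rid, seq, nonstandard=not (_STANDARD >= set(seq))))
    return records


def write_fasta(records: Iterable[FastaRecord | tuple[str, str]],
                stream: IO[str], width: int = 70) -> None:
    for rec in records:
        rid, seq = (rec.id, rec.sequence) if isinstance(rec, FastaRecord) else rec
        stream.write(f">{rid}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i:i + width] + "\n")


def read_truth_table(stream: IO[str]) -> dict[str, dict]:
    """Parse the simulator's truth TSV into read_id -> row dict."""
    import csv

    rows = {}
    header = None
    for line in stream:
        if line.startswith("#coords"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            continue
        if not line.strip():
            continue
        row = dict(zip(header, fields))
        for key in ("start", "end", "length"):
            row[key] = int(row[key])
        rows[row["read_id"]] = row
    return rows
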