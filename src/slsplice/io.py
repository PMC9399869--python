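"""Sequence and table I/O.

FASTA is read through Bio.SeqIO with normalisation suited to transcript and
contig handling: sequences are uppercased, RNA ``U`` is converted to ``T``,
and only the ``{A, C, G, T, N}`` alphabet is accepted.  Tables are plain
UTF-8 TSV with a header row and ``.`` for missing values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_ALLOWED = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (transcript or genomic contig)."""

    id: str
    seq: str
    description: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        if not _ALLOWED.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"record {self.id!r} has non-ACGTN characters: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


def normalize_seq(raw: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return raw.upper().replace("U", "T")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for an
    empty file or duplicate record ids (the offending id is named).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, normalize_seq(str(rec.seq)), desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i:i + wrap] + "\n")


def to_biopython(records: Sequence[SequenceRecord]) -> list[_BioSeqRecord]:
    return [_BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
            for r in records]


def read_tsv(path) -> pd.DataFrame:
    """Read a UTF-8 TSV table with a header row; ``.`` denotes missing."""
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a TSV table; missing values are rendered as ``.``."""
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")
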