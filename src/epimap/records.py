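"""Protein records and FASTA input/output.

A proteome is a list of :class:`ProteinRecord`, one per FASTA entry, with
sequences canonicalized to upper case. Beyond the 20 canonical amino-acid
letters, the ambiguity/rare codes X, B, Z, U and O are tolerated in stored
sequences; downstream motif matching treats them as matching nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity and rare-residue codes accepted in sequences but never matched.
AMBIGUITY_CODES = frozenset("XBZUO")

ALLOWED_SEQUENCE_LETTERS = CANONICAL_RESIDUES | AMBIGUITY_CODES


class FastaFormatError(ValueError):
    """Raised for a structurally invalid FASTA entry; carries the record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, free-text description and residue string."""

    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - ALLOWED_SEQUENCE_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: Union[str, Path]) -> List[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Order is preserved and sequences are upper-cased. An entry with an
    empty sequence, or a duplicate accession, raises
    :class:`FastaFormatError` naming the offending record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[ProteinRecord] = []
    seen = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not rec.id:
            raise FastaFormatError("malformed header (empty id)", i)
        if not seq:
            raise FastaFormatError("empty sequence", i)
        if rec.id in seen:
            raise FastaFormatError(f"duplicate id {rec.id!r}", i)
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, description=rec.description, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path], width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping (deterministic output)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


def to_seqrecords(records: Iterable[ProteinRecord]) -> List[SeqRecord]:
    """Biopython view of a proteome, for interoperability."""
    return [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
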