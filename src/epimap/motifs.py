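"""Fixed-plus-wildcard motif patterns and occurrence scanning.

Patterns are short linear motifs: each slot is either one fixed residue or
a wildcard (written ``x`` or ``.``) that matches any of the 20 canonical
residues. Ambiguity codes (X, B, Z, U, O) satisfy neither fixed nor
wildcard slots, so a window containing one never matches. Coordinates are
0-based, half-open; a hit is C-terminal iff its end equals the protein
length. Overlapping occurrences are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .records import CANONICAL_RESIDUES, ProteinRecord

WILDCARD = None  # slot sentinel

_WILDCARD_CHARS = {"X", "."}


@dataclass(frozen=True)
class MotifPattern:
    """An ordered run of slots, each a fixed residue or a wildcard.

    ``anchor`` restricts where a match may sit: ``"C"`` only at the very
    end of the protein, ``"N"`` only at the start, ``None`` anywhere.
    """

    slots: Tuple[Optional[str], ...]
    anchor: Optional[str] = None  # None | "N" | "C"

    def __post_init__(self):
        if len(self.slots) < 1:
            raise ValueError("pattern requires at least one slot")
        for s in self.slots:
            if s is not None and s not in CANONICAL_RESIDUES:
                raise ValueError(f"fixed slot must be a canonical residue, got {s!r}")
        if self.anchor not in (None, "N", "C"):
            raise ValueError("anchor must be None, 'N' or 'C'")

    @classmethod
    def from_string(cls, text: str, anchor: Optional[str] = None) -> "MotifPattern":
        """Parse e.g. ``"NNI"``, ``"M..........NNI"`` or ``"IILExxR"``.

        Lower-case ``x`` and ``.`` denote wildcards; upper-case letters are
        fixed residues. (Upper-case ``X`` would be the FASTA ambiguity code,
        so wildcards must be written in lower case or as dots.)
        """
        slots: List[Optional[str]] = []
        for ch in text:
            if ch in ("x", "."):
                slots.append(WILDCARD)
            else:
                slots.append(ch.upper())
        return cls(tuple(slots), anchor=anchor)

    def __str__(self) -> str:
        return "".join("x" if s is None else s for s in self.slots)

    @property
    def length(self) -> int:
        return len(self.slots)

    @property
    def n_fixed(self) -> int:
        return sum(1 for s in self.slots if s is not None)

    def matches_at(self, sequence: str, start: int) -> bool:
        """True iff the pattern matches ``sequence[start:start+length]``."""
        end = start + len(self.slots)
        if start < 0 or end > len(sequence):
            return False
        for slot, ch in zip(self.slots, sequence[start:end]):
            if slot is None:
                if ch not in CANONICAL_RESIDUES:
                    return False
            elif ch != slot:
                return False
        return True

    def contains(self, other: "MotifPattern") -> bool:
        """Whether ``other`` occurs as a sub-pattern of this pattern's fixed text."""
        s, o = str(self), str(other)
        return o in s


@dataclass(frozen=True)
class MotifHit:
    """A located occurrence of a pattern within one protein."""

    protein_id: str
    start: int
    end: int
    matched_text: str
    c_terminal: bool

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("hit coordinates must satisfy 0 <= start < end")
        if self.end - self.start != len(self.matched_text):
            raise ValueError("matched_text length must equal end - start")


def scan_motif(protein: ProteinRecord, pattern: MotifPattern) -> List[MotifHit]:
    """All occurrences of ``pattern`` in ``protein``, overlaps included.

    Hits come back in ascending start order. An anchored pattern is checked
    only at its single admissible position.
    """
    seq = protein.sequence
    L, k = len(seq), pattern.length
    if k > L:
        return []
    if pattern.anchor == "N":
        starts: Sequence[int] = (0,)
    elif pattern.anchor == "C":
        starts = (L - k,)
    else:
        starts = range(L - k + 1)
    hits = []
    for s in starts:
        if pattern.matches_at(seq, s):
            e = s + k
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    start=s,
                    end=e,
                    matched_text=seq[s:e],
                    c_terminal=(e == L),
                )
            )
    return hits


def scan_proteome(
    proteome: Sequence[ProteinRecord], pattern: MotifPattern
) -> List[MotifHit]:
    """Concatenated per-protein scans, proteome order preserved."""
    out: List[MotifHit] = []
    for rec in proteome:
        out.extend(scan_motif(rec, pattern))
    return out


def anchored_window_search(
    proteome: Sequence[ProteinRecord], window_pattern: MotifPattern
) -> List[MotifHit]:
    """Find every occurrence of an anchored fixed/wildcard window.

    The canonical use is the 14-residue ``M`` + 10 wildcards + ``NNI``
    window: a methionine, any ten canonical residues, then the motif. The
    window pattern must open and close on fixed slots so that the match
    length is pinned.
    """
    if window_pattern.slots[0] is None or window_pattern.slots[-1] is None:
        raise ValueError("window pattern must have fixed first and last slots")
    return scan_proteome(proteome, window_pattern)
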