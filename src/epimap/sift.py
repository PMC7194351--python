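"""Proteome motif census ("motif-omics") and the Method of Exclusion.

Given a proteome and a short motif (canonically the tripeptide NNI), the
census retains the proteins carrying at least one occurrence — the
"motif-ome" — and tabulates, within it: total occurrences (overlaps
counted), C-terminal occurrences, occurrences of longer sub-patterns that
extend the motif (e.g. FNNI, EFNNI), short proteins, the pool of
non-initiator methionines, anchored M+wildcards+motif windows, and the
survivors of a residue-composition filter.

The Method of Exclusion filters candidate 11-mer windows that begin with
methionine: a window is eliminated if positions 2-11 contain any residue
outside a reference peptide's residue complement (by default the residues
of MKPLTGKVKEF: the excluded set is ARNDCQHISWY, plus a second M, the
first M being spoken for by position 1). Survivors are ranked by how many
distinct reference residues they contain, repeats counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .motifs import MotifHit, MotifPattern, anchored_window_search, scan_motif
from .records import CANONICAL_RESIDUES, ProteinRecord

#: Residue complement of the reference 11-mer (MKPLTGKVKEF), repeats dropped.
DEFAULT_ALLOWED_RESIDUES = frozenset("MKPLTGVEF")

#: Canonical residues absent from the reference peptide.
DEFAULT_EXCLUDED_RESIDUES = frozenset("ARNDCQHISWY")

#: Candidate window length: M plus ten trailing positions.
WINDOW_LENGTH = 11


@dataclass(frozen=True)
class CandidateWindow:
    """An 11-residue M-initial window with its distinct-allowed-residue score."""

    protein_id: str
    start: int
    sequence: str
    distinct_allowed_count: int

    def __post_init__(self):
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(f"window must be {WINDOW_LENGTH} residues")
        if self.sequence[0] != "M":
            raise ValueError("window must start with M")


@dataclass
class SiftReport:
    """Full census of one proteome against one motif."""

    proteome_size: int
    motif_ome_size: int
    total_hits: int
    terminal_hits: int
    sub_pattern_counts: Dict[str, int]
    short_protein_count: int
    methionine_pool: int
    anchored_window_count: int
    anchored_window_hits: List[MotifHit] = field(default_factory=list)
    exclusion_survivors: Dict[int, List[CandidateWindow]] = field(default_factory=dict)

    @property
    def survivor_count(self) -> int:
        return sum(len(v) for v in self.exclusion_survivors.values())

    def survivors_ranked(self) -> List[CandidateWindow]:
        """Survivors sorted by score (desc), ties by (protein_id, start)."""
        out: List[CandidateWindow] = []
        for score in sorted(self.exclusion_survivors, reverse=True):
            out.extend(
                sorted(
                    self.exclusion_survivors[score],
                    key=lambda w: (w.protein_id, w.start),
                )
            )
        return out

    def to_rows(self) -> List[Tuple[str, int]]:
        """Census statistics as (name, value) rows for CSV/report output."""
        rows = [
            ("proteome_size", self.proteome_size),
            ("motif_ome_size", self.motif_ome_size),
            ("total_hits", self.total_hits),
            ("terminal_hits", self.terminal_hits),
            ("short_protein_count", self.short_protein_count),
            ("methionine_pool", self.methionine_pool),
            ("anchored_window_count", self.anchored_window_count),
            ("exclusion_survivor_count", self.survivor_count),
        ]
        for pat, n in sorted(self.sub_pattern_counts.items()):
            rows.append((f"sub_pattern_{pat}", n))
        return rows


def count_methionine_pool(
    proteome: Sequence[ProteinRecord], exclude_initiator: bool = True
) -> int:
    """Total methionines, optionally discounting the position-0 initiator M.

    The initiator is operationalized as the residue at sequence position 0
    of each record; no signal-peptide prediction is attempted.
    """
    total = 0
    for rec in proteome:
        n = rec.sequence.count("M")
        if exclude_initiator and rec.sequence.startswith("M"):
            n -= 1
        total += n
    return total


def candidate_windows(
    proteome: Sequence[ProteinRecord],
    window_length: int = WINDOW_LENGTH,
    exclude_initiator: bool = True,
) -> List[Tuple[str, int, str]]:
    """Every M-initial window of the given length, as (protein_id, start, text).

    One window per methionine that has enough trailing sequence; the
    initiator M (position 0) is skipped when ``exclude_initiator`` is set,
    matching the methionine-pool convention.
    """
    out = []
    for rec in proteome:
        seq = rec.sequence
        first = exclude_initiator and seq.startswith("M")
        for i, ch in enumerate(seq):
            if ch != "M":
                continue
            if first and i == 0:
                continue
            if i + window_length <= len(seq):
                out.append((rec.id, i, seq[i : i + window_length]))
    return out


def _distinct_allowed(window: str, allowed: frozenset) -> int:
    return len(set(window) & allowed)


def method_of_exclusion(
    windows: Sequence[Tuple[str, int, str]],
    allowed_residues: frozenset = DEFAULT_ALLOWED_RESIDUES,
    excluded_extra: frozenset = frozenset("M"),
) -> List[CandidateWindow]:
    """Filter M-initial 11-mers by residue composition and rank survivors.

    A window is rejected when any of its residues 2-11 lies in the
    complement of ``allowed_residues`` within the canonical alphabet, in an
    ambiguity code, or in ``excluded_extra`` (by default a second M). The
    survivors' score is the number of *distinct* residues of the full
    window found in the allowed set. Output is sorted by score descending,
    ties broken by (protein_id, start).

    Raises ``ValueError`` naming the index of any window that does not
    start with M.
    """
    if not allowed_residues <= CANONICAL_RESIDUES:
        raise ValueError("allowed_residues must be canonical amino-acid letters")
    forbidden = (CANONICAL_RESIDUES - allowed_residues) | excluded_extra
    survivors: List[CandidateWindow] = []
    for idx, (pid, start, text) in enumerate(windows):
        if len(text) != WINDOW_LENGTH or not text.startswith("M"):
            raise ValueError(f"window {idx} is not an M-initial {WINDOW_LENGTH}-mer: {text!r}")
        tail = text[1:]
        if any(ch in forbidden or ch not in CANONICAL_RESIDUES for ch in tail):
            continue
        survivors.append(
            CandidateWindow(
                protein_id=pid,
                start=start,
                sequence=text,
                distinct_allowed_count=_distinct_allowed(text, allowed_residues),
            )
        )
    survivors.sort(key=lambda w: (-w.distinct_allowed_count, w.protein_id, w.start))
    return survivors


def build_sift_report(
    proteome: Sequence[ProteinRecord],
    motif: MotifPattern,
    sub_patterns: Sequence[MotifPattern] = (),
    short_threshold: int = 100,
    window_pattern: Optional[MotifPattern] = None,
    allowed_residues: frozenset = DEFAULT_ALLOWED_RESIDUES,
) -> SiftReport:
    """Run the full census: motif-ome, terminal hits, sub-patterns, pools, filter.

    Sub-pattern counts, the short-protein count, the methionine pool, the
    anchored-window search and the exclusion filter are all computed within
    the motif-ome (proteins carrying >= 1 motif occurrence), mirroring the
    two-stage sift: first discount everything without the motif, then mine
    the remainder.
    """
    motif_ome: List[ProteinRecord] = []
    total_hits = 0
    terminal_hits = 0
    for rec in proteome:
        hits = scan_motif(rec, motif)
        if hits:
            motif_ome.append(rec)
            total_hits += len(hits)
            terminal_hits += sum(1 for h in hits if h.c_terminal)

    sub_counts = {
        str(p): sum(len(scan_motif(rec, p)) for rec in motif_ome) for p in sub_patterns
    }
    short_count = sum(1 for rec in motif_ome if rec.length < short_threshold)
    met_pool = count_methionine_pool(motif_ome, exclude_initiator=True)

    window_hits: List[MotifHit] = []
    if window_pattern is not None:
        window_hits = anchored_window_search(motif_ome, window_pattern)

    windows = candidate_windows(motif_ome)
    survivors = method_of_exclusion(windows, allowed_residues=allowed_residues)
    grouped: Dict[int, List[CandidateWindow]] = {}
    for w in survivors:
        grouped.setdefault(w.distinct_allowed_count, []).append(w)

    return SiftReport(
        proteome_size=len(proteome),
        motif_ome_size=len(motif_ome),
        total_hits=total_hits,
        terminal_hits=terminal_hits,
        sub_pattern_counts=sub_counts,
        short_protein_count=short_count,
        methionine_pool=met_pool,
        anchored_window_count=len(window_hits),
        anchored_window_hits=window_hits,
        exclusion_survivors=grouped,
    )


def discount_fraction(proteome_size: int, retained: int) -> float:
    """Percentage of the proteome discounted by keeping only motif carriers."""
    if proteome_size <= 0:
        raise ValueError("proteome_size must be positive")
    return 100.0 * (1.0 - retained / proteome_size)
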