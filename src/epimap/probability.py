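"""Chance-match probability calculus for short linear motifs.

Three families of question arise when a short peptide sequence matches a
protein database entry "suspiciously well":

* **Window matches** — the probability that a random protein of length L,
  with residues drawn i.i.d. from a stated composition, contains a given
  fixed-plus-wildcard pattern in at least one window.
* **Partial anagrams** — the probability that a random k-mer is an ordered
  arrangement of k residues drawn (with multiplicity) from a reference
  residue multiset, computed by exact sub-multiset enumeration with
  multinomial ordering counts.
* **Conditional identities** — e.g. the probability that a random ordered
  k-permutation of the multiset begins with a particular residue, which
  equals multiplicity / multiset size by a symmetry argument.

Independent small probabilities multiply; results carry a human-readable
"1 in N" rendering whose rounding granularity coarsens with N.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .motifs import MotifPattern
from .records import CANONICAL_RESIDUES

__all__ = [
    "ResidueComposition",
    "ChanceMatchResult",
    "AnagramSpec",
    "per_window_prob",
    "protein_match_prob",
    "combined_independent_odds",
    "anagram_window_prob",
    "anagram_match_count",
    "initial_residue_conditional_prob",
    "empirical_database_prob",
    "render_one_in",
    "parse_one_in",
]


@dataclass(frozen=True)
class ResidueComposition:
    """Residue frequencies; defaults to the uniform 1/20 alphabet model."""

    frequencies: Mapping[str, float] = field(
        default_factory=lambda: {aa: 1.0 / 20.0 for aa in sorted(CANONICAL_RESIDUES)}
    )

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if any(p < 0 for p in self.frequencies.values()):
            raise ValueError("residue frequencies must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies must sum to 1 (got {total})")

    def __getitem__(self, residue: str) -> float:
        return self.frequencies.get(residue, 0.0)

    @property
    def alphabet(self) -> Tuple[str, ...]:
        return tuple(sorted(self.frequencies))


def render_one_in(probability: float) -> str:
    """Render a probability as "1 in N", coarsening with magnitude.

    N >= 1e7 rounds to the nearest million ("1 in 14m"); N >= 1e6 to the
    nearest hundred thousand ("1 in 1.6m"); N >= 1e5 to the nearest
    thousand ("1 in 146,000"); otherwise to the nearest integer. A zero
    probability has no reciprocal and renders as "never by this model".
    """
    if probability < 0 or probability > 1:
        raise ValueError("probability must lie in [0, 1]")
    if probability == 0:
        return "never by this model"
    n = 1.0 / probability
    if n >= 1e7:
        millions = round(n / 1e6)
        return f"1 in {millions}m"
    if n >= 1e6:
        tenths = round(n / 1e5) / 10.0
        return f"1 in {tenths:g}m"
    if n >= 1e5:
        return f"1 in {round(n / 1e3) * 1000:,}"
    return f"1 in {round(n):,}"


def parse_one_in(text: str) -> float:
    """Inverse of :func:`render_one_in` up to its rounding granularity."""
    m = re.fullmatch(r"1 in ([\d.,]+)(m?)", text.strip())
    if not m:
        raise ValueError(f"cannot parse odds rendering {text!r}")
    value = float(m.group(1).replace(",", ""))
    if m.group(2) == "m":
        value *= 1e6
    return 1.0 / value


@dataclass(frozen=True)
class ChanceMatchResult:
    """Per-protein chance-match summary under the i.i.d. window model."""

    per_window_prob: float
    n_windows: int
    expected_occurrences: float
    prob_at_least_one: float

    @property
    def reciprocal_odds(self) -> str:
        return render_one_in(self.prob_at_least_one)


def per_window_prob(
    pattern: MotifPattern, composition: Optional[ResidueComposition] = None
) -> float:
    """Probability one random window matches: product of fixed-slot frequencies."""
    comp = composition or ResidueComposition()
    p = 1.0
    for slot in pattern.slots:
        if slot is not None:
            p *= comp[slot]
    return p


def protein_match_prob(
    pattern: MotifPattern,
    protein_length: int,
    composition: Optional[ResidueComposition] = None,
) -> ChanceMatchResult:
    """Chance of >= 1 pattern occurrence in a random protein of given length.

    Windows are treated as independent, so
    ``prob_at_least_one = 1 - (1 - p)^n`` with ``n = L - k + 1`` windows.
    For short patterns and small p this is accurate to well within the
    rendering granularity; a Monte-Carlo check is part of the test suite.
    """
    if protein_length < 0:
        raise ValueError("protein_length must be non-negative")
    p = per_window_prob(pattern, composition)
    n = max(0, protein_length - pattern.length + 1)
    expected = n * p
    prob = 1.0 - (1.0 - p) ** n if n > 0 else 0.0
    return ChanceMatchResult(
        per_window_prob=p,
        n_windows=n,
        expected_occurrences=expected,
        prob_at_least_one=prob,
    )


def combined_independent_odds(p1: float, p2: float) -> Tuple[float, str]:
    """Product of two independent match probabilities, with rendering.

    Odds quoted as "1 in N" enter as ``1/N``; e.g. combining 1/5,247 and
    1/2,636 yields ~1 in 14 million.
    """
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    combined = p1 * p2
    return combined, render_one_in(combined)


@dataclass(frozen=True)
class AnagramSpec:
    """A residue multiset and a window length k for partial-anagram questions."""

    multiset: Mapping[str, int]
    window_len: int

    def __post_init__(self):
        if any(m < 1 for m in self.multiset.values()):
            raise ValueError("multiplicities must be >= 1")
        if self.window_len > self.size:
            raise ValueError("window length exceeds multiset size")
        if self.window_len < 0:
            raise ValueError("window length must be >= 0")

    @classmethod
    def from_sequence(cls, sequence: str, window_len: int) -> "AnagramSpec":
        counts: Dict[str, int] = {}
        for ch in sequence.upper():
            counts[ch] = counts.get(ch, 0) + 1
        return cls(counts, window_len)

    @property
    def size(self) -> int:
        return sum(self.multiset.values())


def anagram_match_count(spec: AnagramSpec) -> int:
    """Number of distinct ordered k-mers drawing their letters from the multiset.

    Exact: sum over all k-element sub-multisets (count vectors c with
    ``0 <= c_i <= m_i`` and ``sum c_i = k``) of the multinomial ordering
    count ``k! / prod(c_i!)``. Each ordered string determines its own count
    vector, so no string is counted twice.
    """
    mults = list(spec.multiset.values())
    k = spec.window_len

    # Exact integer arithmetic: accumulate k!/prod(c_i!) directly.
    def count(i: int, remaining: int, denom: int) -> int:
        if remaining == 0:
            return math.factorial(k) // denom
        if i == len(mults):
            return 0
        total = 0
        for c in range(0, min(mults[i], remaining) + 1):
            total += count(i + 1, remaining - c, denom * math.factorial(c))
        return total

    return count(0, k, 1)


def anagram_window_prob(
    spec: AnagramSpec, composition: Optional[ResidueComposition] = None
) -> float:
    """Per-window probability that a random k-mer is a partial anagram.

    Under a uniform composition over an alphabet of size A this is
    ``anagram_match_count / A^k``. Non-uniform compositions sum the
    probability of each admissible ordered string; letters outside the
    multiset contribute nothing.
    """
    k = spec.window_len
    if k == 0:
        return 1.0
    comp = composition or ResidueComposition()
    probs = {aa: comp[aa] for aa in spec.multiset}
    uniform = len(set(np.round([comp[a] for a in comp.alphabet], 15))) == 1
    if uniform:
        a = len(comp.alphabet)
        return anagram_match_count(spec) / float(a) ** k
    # general case: weighted sum over count vectors
    letters = list(spec.multiset)
    mults = [spec.multiset[l] for l in letters]

    def rec(i: int, remaining: int, denom: int, weight: float) -> float:
        if remaining == 0:
            return math.factorial(k) / denom * weight
        if i == len(letters):
            return 0.0
        total = 0.0
        for c in range(0, min(mults[i], remaining) + 1):
            total += rec(
                i + 1,
                remaining - c,
                denom * math.factorial(c),
                weight * probs[letters[i]] ** c,
            )
        return total

    return rec(0, k, 1, 1.0)


def initial_residue_conditional_prob(spec: AnagramSpec, residue: str) -> float:
    """Probability a random ordered k-permutation of the multiset starts with ``residue``.

    Drawing k items without replacement from the multiset and reading them
    in order, the first item is a uniformly random element of the multiset,
    so the probability is multiplicity / size — e.g. 1/11 for the single M
    among 11 residues. Returns 0 for a residue absent from the multiset.
    """
    if spec.window_len < 1:
        raise ValueError("window length must be >= 1 for an initial residue")
    return spec.multiset.get(residue, 0) / spec.size


def empirical_database_prob(proteome, pattern: MotifPattern) -> Tuple[float, str]:
    """Census fraction of database proteins containing >= 1 pattern match."""
    from .motifs import scan_motif

    proteome = list(proteome)
    if not proteome:
        raise ValueError("empty proteome")
    hits = sum(1 for rec in proteome if scan_motif(rec, pattern))
    frac = hits / len(proteome)
    return frac, render_one_in(frac)
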