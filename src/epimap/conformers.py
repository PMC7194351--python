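"""Comparison of peptide conformers via labelled interatomic-distance tables.

Each conformer is summarised by the pairwise distances (in Angstroms)
between a small set of hand-picked atoms labelled with single letters
(a, b, c, ...). Two conformers are compared with the descriptive statistic
``sum((O - E)^2 / E)`` over the shared pair labels, with the "expected"
table E taken from the reference conformer (the epitope as embedded in the
full peptide) and the "observed" table O from the free peptide. The
statistic is referred to a chi-squared distribution with ``n_pairs - 1``
degrees of freedom to yield a similar/dissimilar verdict, and the fraction
of pairs with a squared difference above a threshold (default 10 A^2) is
reported as the "big difference" proportion.

Note the statistic is a descriptive index on distances, not a count-based
chi-squared; the distributional verdict follows the field convention of
reading it against chi-squared quantiles regardless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AtomSelection",
    "DistanceTable",
    "ConformerComparison",
    "chi_squared_compare",
    "significance_verdict",
    "big_diff_proportion",
    "distances_from_coordinates",
    "read_distance_csv",
    "write_distance_csv",
]


@dataclass(frozen=True)
class AtomSelection:
    """One labelled atom: letter label, residue tag (e.g. K9), description."""

    label: str
    residue_tag: str
    atom_descriptor: str = ""


def _norm_pair(pair: str) -> str:
    """Canonicalize an unordered pair label: 'b-a' -> 'a-b'."""
    parts = pair.split("-")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"pair label must be like 'a-b', got {pair!r}")
    a, b = parts
    if a == b:
        raise ValueError(f"pair label joins an atom to itself: {pair!r}")
    return f"{min(a, b)}-{max(a, b)}"


@dataclass
class DistanceTable:
    """Labelled pairwise interatomic distances for one peptide conformer."""

    peptide_name: str
    entries: Dict[str, float]

    def __post_init__(self):
        normed: Dict[str, float] = {}
        for pair, d in self.entries.items():
            key = _norm_pair(pair)
            if key in normed:
                raise ValueError(f"duplicate pair label {key!r}")
            if not d > 0:
                raise ValueError(f"distance for {key!r} must be positive, got {d}")
            normed[key] = float(d)
        self.entries = normed

    @property
    def n_pairs(self) -> int:
        return len(self.entries)

    @property
    def pair_labels(self) -> frozenset:
        return frozenset(self.entries)

    def subset(self, pairs: Iterable[str]) -> "DistanceTable":
        pairs = [_norm_pair(p) for p in pairs]
        missing = [p for p in pairs if p not in self.entries]
        if missing:
            raise KeyError(f"pairs absent from table {self.peptide_name!r}: {missing}")
        return DistanceTable(self.peptide_name, {p: self.entries[p] for p in pairs})


@dataclass(frozen=True)
class ConformerComparison:
    """Result of comparing an observed conformer against an expected one."""

    observed_name: str
    expected_name: str
    chi_squared: float
    dof: int
    proportion_big_diff: float
    threshold: float
    confidence: float
    critical_value: float
    verdict: str  # "indistinguishable" | "distinct"


def _check_aligned(observed: DistanceTable, expected: DistanceTable) -> List[str]:
    if observed.pair_labels != expected.pair_labels:
        only_o = sorted(observed.pair_labels - expected.pair_labels)
        only_e = sorted(expected.pair_labels - observed.pair_labels)
        raise ValueError(
            "pair-label sets differ: "
            f"only in observed {only_o}; only in expected {only_e}"
        )
    if observed.n_pairs < 2:
        raise ValueError("need at least 2 shared pairs to compare")
    return sorted(observed.pair_labels)


def big_diff_proportion(
    observed: DistanceTable, expected: DistanceTable, threshold: float = 10.0
) -> float:
    """Fraction of pairs with (O - E)^2 strictly above ``threshold`` (A^2)."""
    pairs = _check_aligned(observed, expected)
    sq = np.array([(observed.entries[p] - expected.entries[p]) ** 2 for p in pairs])
    return float(np.mean(sq > threshold))


def significance_verdict(
    chi_squared: float, dof: int, confidence: float = 0.995
) -> Tuple[str, float]:
    """Similar/dissimilar call against the chi-squared quantile.

    Returns ("indistinguishable", quantile) when the statistic is below the
    chi-squared quantile at the given confidence for ``dof`` degrees of
    freedom, else ("distinct", quantile).
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    critical = float(stats.chi2.ppf(confidence, dof))
    verdict = "indistinguishable" if chi_squared < critical else "distinct"
    return verdict, critical


def chi_squared_compare(
    observed: DistanceTable,
    expected: DistanceTable,
    threshold: float = 10.0,
    confidence: float = 0.995,
) -> ConformerComparison:
    """Full comparison: statistic, dof, big-difference proportion, verdict."""
    pairs = _check_aligned(observed, expected)
    o = np.array([observed.entries[p] for p in pairs])
    e = np.array([expected.entries[p] for p in pairs])
    chi2 = float(np.sum((o - e) ** 2 / e))
    dof = len(pairs) - 1
    prop = big_diff_proportion(observed, expected, threshold)
    verdict, critical = significance_verdict(chi2, dof, confidence)
    return ConformerComparison(
        observed_name=observed.peptide_name,
        expected_name=expected.peptide_name,
        chi_squared=chi2,
        dof=dof,
        proportion_big_diff=prop,
        threshold=threshold,
        confidence=confidence,
        critical_value=critical,
        verdict=verdict,
    )


def distances_from_coordinates(
    coordinates: Mapping[str, Sequence[float]],
    peptide_name: str = "model",
    pairs: Optional[Iterable[str]] = None,
) -> DistanceTable:
    """Euclidean distance table from labelled 3-D points.

    With ``pairs`` unset, every unordered pair of labels is measured
    (n*(n-1)/2 entries); otherwise only the named subset, allowing the
    hand-curated pair lists used for published measurement sets.
    """
    pts = {label: np.asarray(xyz, dtype=float) for label, xyz in coordinates.items()}
    for label, p in pts.items():
        if p.shape != (3,):
            raise ValueError(f"coordinate for {label!r} must be a 3-vector")
    if pairs is None:
        pair_list = [f"{a}-{b}" for a, b in itertools.combinations(sorted(pts), 2)]
    else:
        pair_list = [_norm_pair(p) for p in pairs]
    entries = {}
    for pair in pair_list:
        a, b = pair.split("-")
        if a not in pts or b not in pts:
            missing = [x for x in (a, b) if x not in pts]
            raise KeyError(f"no coordinates for label(s) {missing}")
        entries[pair] = float(np.linalg.norm(pts[a] - pts[b]))
    return DistanceTable(peptide_name, entries)


def coordinates_from_pdb(
    path: Union[str, Path], selections: Mapping[str, Tuple[int, str]]
) -> Dict[str, Tuple[float, float, float]]:
    """Pick labelled atom coordinates out of a single-model PDB file.

    ``selections`` maps each single-letter label to (residue sequence
    number, atom name), e.g. ``{"a": (9, "NZ")}`` for the side-chain
    nitrogen of K9. Raises ``KeyError`` for a selection the model does not
    contain.
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("model", str(path))
    model = next(iter(structure))
    by_resseq = {}
    for chain in model:
        for residue in chain:
            by_resseq[residue.id[1]] = residue
    out: Dict[str, Tuple[float, float, float]] = {}
    for label, (resseq, atom_name) in selections.items():
        if resseq not in by_resseq or atom_name not in by_resseq[resseq]:
            raise KeyError(f"selection {label!r}: no atom {atom_name} in residue {resseq}")
        out[label] = tuple(float(x) for x in by_resseq[resseq][atom_name].coord)
    return out


def read_distance_csv(path: Union[str, Path]) -> Dict[str, DistanceTable]:
    """Read one or more peptides' distance tables from a CSV file.

    Expected columns: ``peptide``, ``pair`` (like ``a-b``), and
    ``distance_angstrom``; ``atom_from``/``atom_to`` are accepted in place
    of ``pair``. Returns a mapping from peptide name to table.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "pair" not in cols and {"atom_from", "atom_to"} <= set(cols):
        df["pair"] = (
            df[cols["atom_from"]].astype(str).str.strip()
            + "-"
            + df[cols["atom_to"]].astype(str).str.strip()
        )
        cols["pair"] = "pair"
    for needed in ("peptide", "pair", "distance_angstrom"):
        if needed not in cols:
            raise ValueError(f"distance CSV lacks column {needed!r}")
    tables: Dict[str, DistanceTable] = {}
    for name, grp in df.groupby(cols["peptide"], sort=False):
        entries = dict(
            zip(grp[cols["pair"]].astype(str), grp[cols["distance_angstrom"]].astype(float))
        )
        tables[str(name)] = DistanceTable(str(name), entries)
    return tables


def write_distance_csv(
    tables: Iterable[DistanceTable], path: Union[str, Path]
) -> None:
    rows = []
    for t in tables:
        for pair in sorted(t.entries):
            a, b = pair.split("-")
            rows.append(
                {
                    "peptide": t.peptide_name,
                    "pair": pair,
                    "atom_from": a,
                    "atom_to": b,
                    "distance_angstrom": t.entries[pair],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
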