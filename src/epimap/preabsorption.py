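"""Preabsorption-panel analysis: staining quantification and epitope inference.

In a preabsorption experiment an antibody is pre-incubated with a
competing synthetic peptide before tissue staining; loss of staining means
the peptide carries the antibody's epitope. This module covers the whole
readout chain:

* area-fraction quantification of grayscale staining images at a fixed
  intensity threshold;
* percent-of-control normalisation against the peptide-free condition;
* replicate summaries (mean +/- SEM) and unpaired t-tests (pooled-variance
  Student by default, Welch optionally), accepting raw replicates or
  (n, mean, SEM) summaries interchangeably;
* IC50 reported as a bound over the tested doses ("<= 10 ng/ml" style),
  with an optional logistic curve fit for synthetic-data validation;
* inference of the epitope's C-terminal suffix pattern from a panel of
  blockers and non-blockers, by exhaustive scoring of fixed/wildcard
  suffix patterns, plus a second-pass single-substitution scan that flags
  residues required for blockade but outside the contiguous core.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PanelEntry",
    "StainingMeasurement",
    "GroupSummary",
    "TTestResult",
    "SuffixPattern",
    "EpitopeInference",
    "IC50Bound",
    "area_fraction",
    "percent_of_control",
    "summarize",
    "unpaired_t",
    "ic50_bound",
    "fit_inhibition_curve",
    "infer_epitope",
    "substitution_scan",
]

BLOCK_CATEGORIES = ("yes", "no", "partial", "highest-conc-only")


@dataclass(frozen=True)
class PanelEntry:
    """One panel peptide: code, sequence and blockade outcome.

    ``variant_of`` marks single-substitution variants of another panel
    peptide (e.g. alanine-substituted tetramers); these are analysed in
    the substitution scan, not in the suffix-pattern search.
    """

    peptide_code: str
    sequence: str
    blocks: str
    variant_of: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("panel entry requires a non-empty sequence")
        if self.blocks not in BLOCK_CATEGORIES:
            raise ValueError(f"blocks must be one of {BLOCK_CATEGORIES}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class StainingMeasurement:
    """One image's staining quantification under one condition."""

    image_id: str
    tissue: str
    peptide_code: str
    concentration: float  # ng/ml; 0 for the peptide-free control
    area_labelled: float  # fraction of pixels above threshold
    percent_of_control: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.area_labelled <= 1.0:
            raise ValueError("area_labelled must lie in [0, 1]")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class GroupSummary:
    """Replicate summary: n, mean, and SEM (sample SD / sqrt(n); 0 when n = 1)."""

    n: int
    mean: float
    sem: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n == 1 and self.sem != 0:
            raise ValueError("sem must be 0 when n = 1")


@dataclass(frozen=True)
class TTestResult:
    t: float
    dof: float
    p: float
    variant: str  # "pooled" | "welch"


def area_fraction(
    image: Union[np.ndarray, str, Path], threshold: float
) -> float:
    """Fraction of pixels with intensity strictly above ``threshold``.

    ``image`` may be a 2-D array or a path to a grayscale PNG/TIFF; a
    colour image is rejected rather than silently converted.
    """
    if isinstance(image, (str, Path)):
        from PIL import Image

        with Image.open(image) as im:
            arr = np.asarray(im.convert("I") if im.mode not in ("L", "I", "F") and len(im.getbands()) == 1 else im)
    else:
        arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel (grayscale) image")
    if arr.size == 0:
        raise ValueError("empty image")
    return float(np.mean(arr > threshold))


def percent_of_control(
    measurements: Sequence[StainingMeasurement], control_key: str
) -> List[StainingMeasurement]:
    """Express each area as a percentage of the mean peptide-free control area.

    The control group's own mean maps to exactly 100. Returns annotated
    copies; input order is preserved.
    """
    control_areas = [m.area_labelled for m in measurements if m.peptide_code == control_key]
    if not control_areas:
        raise ValueError(f"no control measurements with peptide_code {control_key!r}")
    control_mean = float(np.mean(control_areas))
    if control_mean == 0:
        raise ValueError("control mean area is zero; cannot normalise")
    return [
        replace(m, percent_of_control=100.0 * m.area_labelled / control_mean)
        for m in measurements
    ]


def summarize(groups: Mapping[str, Sequence[float]]) -> Dict[str, GroupSummary]:
    """Per-group mean and SEM (sample SD with n-1 denominator over sqrt n)."""
    out = {}
    for key, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size < 1:
            raise ValueError(f"group {key!r} is empty")
        sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
        out[key] = GroupSummary(n=int(v.size), mean=float(np.mean(v)), sem=sem)
    return out


def _as_summary(group) -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    return summarize({"_": group})["_"]


def unpaired_t(group_a, group_b, variant: str = "pooled") -> TTestResult:
    """Two-sided unpaired t-test from raw replicates or (n, mean, SEM) summaries.

    Summaries computed from the raw values give identical results to the
    raw values themselves, since the test depends on the data only through
    (n, mean, SD). Both groups need n >= 2 for a variance estimate. When
    both variances are zero: equal means give t = 0, p = 1; unequal means
    are degenerate and raise.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    a, b = _as_summary(group_a), _as_summary(group_b)
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    var_a = (a.sem * math.sqrt(a.n)) ** 2
    var_b = (b.sem * math.sqrt(b.n)) ** 2
    if var_a == 0 and var_b == 0:
        if a.mean == b.mean:
            dof = a.n + b.n - 2 if variant == "pooled" else float(a.n + b.n - 2)
            return TTestResult(t=0.0, dof=dof, p=1.0, variant=variant)
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "pooled":
        dof = a.n + b.n - 2
        sp2 = ((a.n - 1) * var_a + (b.n - 1) * var_b) / dof
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        se2_a, se2_b = var_a / a.n, var_b / b.n
        se = math.sqrt(se2_a + se2_b)
        dof = (se2_a + se2_b) ** 2 / (
            se2_a**2 / (a.n - 1) + se2_b**2 / (b.n - 1)
        )
    t = (a.mean - b.mean) / se
    p = float(2 * stats.t.sf(abs(t), dof))
    return TTestResult(t=float(t), dof=float(dof), p=min(p, 1.0), variant=variant)


@dataclass(frozen=True)
class IC50Bound:
    """IC50 reported as a bound over the tested doses.

    ``kind`` is one of ``"le"`` (<= concentration: first tested dose at
    which the mean drops to 50% or below), ``"lt_min"`` (< lowest tested
    dose: already at or below 50% at the bottom of the range) or
    ``"not_reached"``.
    """

    kind: str
    concentration: Optional[float]

    def __str__(self) -> str:
        if self.kind == "le":
            return f"<= {self.concentration:g} ng/ml"
        if self.kind == "lt_min":
            return f"< {self.concentration:g} ng/ml"
        return "not reached"

    @property
    def sort_value(self) -> float:
        """Orderable surrogate: lower bound value means a more potent blocker."""
        if self.kind == "not_reached":
            return math.inf
        if self.kind == "lt_min":
            return self.concentration / 2.0
        return self.concentration


def ic50_bound(dose_response: Sequence[Tuple[float, float]]) -> IC50Bound:
    """Bound the IC50 from (concentration, mean percent-of-control) points.

    No monotone trend is assumed: the bound is the smallest tested
    concentration whose mean is at or below 50%.
    """
    if len(dose_response) < 2:
        raise ValueError("need at least two tested concentrations")
    points = sorted(dose_response)
    cmin = points[0][0]
    for conc, pct in points:
        if pct <= 50.0:
            if conc == cmin:
                return IC50Bound("lt_min", cmin)
            return IC50Bound("le", conc)
    return IC50Bound("not_reached", None)


def _logistic(c, ic50, slope):
    return 100.0 / (1.0 + (c / ic50) ** slope)


def fit_inhibition_curve(
    concentrations: Sequence[float], percents: Sequence[float]
) -> Tuple[float, float]:
    """Least-squares (IC50, slope) of a logistic inhibition curve.

    Floor 0 and ceiling 100 are held fixed. Intended for validating
    synthetic dose-response data, not for reporting experimental IC50s,
    which are quoted as bounds.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(percents, dtype=float)
    p0 = (float(np.median(c)), 1.0)
    popt, _ = optimize.curve_fit(
        _logistic, c, y, p0=p0, bounds=([1e-9, 0.05], [np.inf, 20.0]), maxfev=10000
    )
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Suffix-pattern inference


@dataclass(frozen=True)
class SuffixPattern:
    """A C-terminally anchored fixed/wildcard pattern.

    ``slots`` run N-to-C over the suffix; the last slot sits on the
    peptide's final residue. A peptide matches iff it is at least as long
    as the pattern and every fixed slot agrees.
    """

    slots: Tuple[Optional[str], ...]

    def __post_init__(self):
        if len(self.slots) < 1:
            raise ValueError("suffix pattern needs >= 1 slot")
        if all(s is None for s in self.slots):
            raise ValueError("suffix pattern needs >= 1 fixed slot")

    @classmethod
    def from_string(cls, text: str) -> "SuffixPattern":
        return cls(tuple(None if ch in ("x", ".") else ch.upper() for ch in text))

    def __str__(self) -> str:
        return "".join("x" if s is None else s for s in self.slots)

    @property
    def length(self) -> int:
        return len(self.slots)

    @property
    def n_fixed(self) -> int:
        return sum(1 for s in self.slots if s is not None)

    def matches(self, sequence: str) -> bool:
        if len(sequence) < self.length:
            return False
        tail = sequence[-self.length :]
        return all(s is None or s == ch for s, ch in zip(self.slots, tail))


@dataclass(frozen=True)
class PatternScore:
    pattern: SuffixPattern
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class EpitopeInference:
    """Ranked suffix patterns and the residue-level epitope classification."""

    ranked: List[PatternScore]
    best: Optional[SuffixPattern]
    degenerate: bool = False
    residue_classification: Dict[int, str] = field(default_factory=dict)
    n_blockers: int = 0
    n_non_blockers: int = 0

    @property
    def best_score(self) -> Optional[PatternScore]:
        return self.ranked[0] if self.ranked else None


def _partition_panel(
    panel: Sequence[PanelEntry],
    partial_as_blocker: bool = True,
    include_highest_conc_only: bool = False,
) -> Tuple[List[PanelEntry], List[PanelEntry]]:
    blockers, non_blockers = [], []
    for e in panel:
        if e.variant_of is not None and not (
            include_highest_conc_only and e.blocks == "highest-conc-only"
        ):
            continue
        if e.blocks == "yes" or (e.blocks == "partial" and partial_as_blocker):
            blockers.append(e)
        elif e.blocks == "highest-conc-only":
            if include_highest_conc_only:
                blockers.append(e)
        else:
            non_blockers.append(e)
    return blockers, non_blockers


def infer_epitope(
    panel: Sequence[PanelEntry],
    max_len: int = 6,
    partial_as_blocker: bool = True,
    include_highest_conc_only: bool = False,
    top_k: int = 25,
    substitution_results: Optional[Mapping[str, bool]] = None,
) -> EpitopeInference:
    """Infer the blockade-separating C-terminal suffix pattern from a panel.

    Every fixed/wildcard suffix pattern up to ``max_len`` slots is scored
    by the accuracy of the rule "blocks iff the pattern matches the
    peptide's C-terminus"; candidate fixed residues at each slot are those
    observed at that C-terminal offset in the panel (any other choice
    matches no peptide there and is dominated). Ranking is by accuracy
    (desc), fixed-slot count (desc), length (asc), then pattern string —
    total and deterministic. Entries marked as substitution variants and,
    by default, highest-concentration-only blockers stay out of the
    search.

    A panel whose peptides all carry the same label cannot separate
    anything: the inference is returned flagged degenerate with no best
    pattern (the implicit all-wildcard rule).

    With ``substitution_results`` (peptide sequence -> blocked?) the
    per-residue classification distinguishes the contiguous core (fixed
    slots of the best pattern) from residues that substitution shows to be
    required without being part of the core, and from dispensable ones.
    """
    blockers, non_blockers = _partition_panel(
        panel, partial_as_blocker, include_highest_conc_only
    )
    if not blockers or not non_blockers:
        return EpitopeInference(
            ranked=[],
            best=None,
            degenerate=True,
            n_blockers=len(blockers),
            n_non_blockers=len(non_blockers),
        )

    entries = blockers + non_blockers
    n = len(entries)
    blocker_mask = (1 << len(blockers)) - 1
    full_mask = (1 << n) - 1

    # Bitmask per (offset-from-C, residue): which peptides carry that
    # residue at that offset. Offset 0 is the final residue.
    slot_masks: List[Dict[Optional[str], int]] = []
    len_masks: List[int] = []  # peptides long enough for a pattern of length L
    for off in range(max_len):
        masks: Dict[Optional[str], int] = {}
        lm = 0
        for i, e in enumerate(entries):
            if len(e.sequence) > off:
                ch = e.sequence[-(off + 1)]
                masks[ch] = masks.get(ch, 0) | (1 << i)
                lm |= 1 << i
        masks[None] = lm  # wildcard at this offset: any residue, but must exist
        slot_masks.append(masks)
        len_masks.append(lm)

    n_block, n_non = len(blockers), len(non_blockers)
    scored: List[Tuple[float, int, int, str, SuffixPattern, float, float]] = []
    for length in range(1, max_len + 1):
        # choices[j] covers offset j from the C terminus, j = 0..length-1
        per_slot = [sorted(slot_masks[j], key=lambda s: (s is None, s)) for j in range(length)]
        for combo in itertools.product(*per_slot):
            if all(s is None for s in combo):
                continue
            mask = len_masks[length - 1]
            for j, s in enumerate(combo):
                mask &= slot_masks[j][s]
                if not mask:
                    break
            matched_blockers = (mask & blocker_mask).bit_count()
            matched_non = (mask >> n_block).bit_count()
            tp = matched_blockers
            tn = n_non - matched_non
            accuracy = (tp + tn) / n
            # slots N-to-C: reverse the offset order
            pat = SuffixPattern(tuple(reversed(combo)))
            scored.append(
                (
                    -accuracy,
                    -pat.n_fixed,
                    pat.length,
                    str(pat),
                    pat,
                    tp / n_block,
                    tn / n_non,
                )
            )
    scored.sort(key=lambda r: r[:4])
    ranked = [
        PatternScore(pattern=r[4], accuracy=-r[0], sensitivity=r[5], specificity=r[6])
        for r in scored[:top_k]
    ]
    best = ranked[0].pattern if ranked else None

    classification: Dict[int, str] = {}
    if best is not None:
        for i, s in enumerate(reversed(best.slots)):  # i = offset from C terminus
            if s is not None:
                classification[i + 1] = "contiguous-core"
        if substitution_results:
            for pos, required in substitution_scan(substitution_results).items():
                if pos not in classification:
                    classification[pos] = (
                        "required-non-contiguous" if required else "dispensable"
                    )
    return EpitopeInference(
        ranked=ranked,
        best=best,
        degenerate=False,
        residue_classification=classification,
        n_blockers=n_block,
        n_non_blockers=n_non,
    )


def panel_from_measurements(
    measurements,
    sequences: Mapping[str, str],
    blockade_threshold: float = 50.0,
) -> List[PanelEntry]:
    """Call blockade from titration measurements and build a panel.

    ``measurements`` is a tidy table (DataFrame or list of dicts) with
    columns ``peptide_code``, ``concentration_ng_ml`` and
    ``percent_of_control``. A peptide blocks ("yes") when its mean percent
    of control at the highest tested concentration is at or below the
    threshold; "highest-conc-only" is never called here (that category
    comes from qualitative panel tables). Control rows (concentration 0)
    are ignored.
    """
    import pandas as pd

    df = pd.DataFrame(measurements)
    df = df[df["concentration_ng_ml"] > 0]
    entries = []
    for code, grp in df.groupby("peptide_code", sort=True):
        if code not in sequences:
            raise KeyError(f"no sequence for peptide {code!r}")
        top = grp["concentration_ng_ml"].max()
        mean_top = grp.loc[grp["concentration_ng_ml"] == top, "percent_of_control"].mean()
        blocks = "yes" if mean_top <= blockade_threshold else "no"
        entries.append(PanelEntry(str(code), sequences[code], blocks))
    return entries


def substitution_scan(results: Mapping[str, bool]) -> Dict[int, bool]:
    """Which positions does single-residue substitution show to be required?

    ``results`` maps peptide sequences of equal length — a reference plus
    single-substitution variants — to whether each still blocks. The
    reference is the blocking sequence from which every other differs at
    exactly one position. Returns {position from C terminus (1 = last):
    required?}: a position is required iff substituting it abolishes
    blockade.
    """
    seqs = list(results)
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("all sequences must share one length")
    blocked = [s for s in seqs if results[s]]
    if not blocked:
        raise ValueError("no blocking sequence to serve as reference")

    def diff_positions(a: str, b: str) -> List[int]:
        return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]

    reference = None
    for cand in blocked:
        if all(len(diff_positions(cand, s)) == 1 for s in seqs if s != cand):
            reference = cand
            break
    if reference is None:
        raise ValueError("no sequence differs from all others at exactly one position")

    out: Dict[int, bool] = {}
    L = len(reference)
    for s in seqs:
        if s == reference:
            continue
        (pos,) = diff_positions(reference, s)
        out[L - pos] = not results[s]
    return out
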