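"""Ground-truth synthetic data: proteomes, distance tables, panels, images.

Every generator is deterministic under a fixed seed and emits the truth
alongside the artifact, so the census, probability, conformer and
preabsorption analyses can be validated end to end without any external
database. The proteome generator rejection-samples the background so that
planted motif occurrences are the *only* occurrences of the planted
patterns, making manifest counts exact rather than merely expected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .motifs import MotifPattern
from .preabsorption import SuffixPattern
from .probability import ResidueComposition
from .records import ProteinRecord, write_fasta
from .sift import SiftReport, build_sift_report
from .conformers import DistanceTable

__all__ = [
    "PlantSpec",
    "SyntheticProteomeSpec",
    "GroundTruthManifest",
    "make_proteome",
    "make_distance_tables",
    "SyntheticPanelSpec",
    "make_panel_measurements",
    "make_images",
]

PLACEMENTS = ("internal", "C-terminal", "anchored-window")


@dataclass(frozen=True)
class PlantSpec:
    """One planting instruction: pattern text, occurrence count, placement."""

    pattern: str
    count: int
    placement: str = "internal"

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Recipe for a proteome with planted motif occurrences.

    Defaults emulate a small motif census: 50 proteins of 80-400 residues
    under the uniform composition, with 12 internal and 2 C-terminal NNIs
    plus 3 anchored M+10x+NNI windows planted.
    """

    n_proteins: int = 50
    min_length: int = 80
    max_length: int = 400
    composition: ResidueComposition = field(default_factory=ResidueComposition)
    plants: Tuple[PlantSpec, ...] = (
        PlantSpec("NNI", 12, "internal"),
        PlantSpec("NNI", 2, "C-terminal"),
        PlantSpec("MxxxxxxxxxxNNI", 3, "anchored-window"),
    )
    seed: int = 1

    def __post_init__(self):
        if self.n_proteins < 0 or self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid proteome dimensions")


@dataclass
class GroundTruthManifest:
    """Planted coordinates plus the census report of the emitted proteome.

    ``planted``: pattern text -> list of (protein_id, start).
    ``report`` re-verifies by re-scanning the FASTA; because of rejection
    sampling the planted coordinates are the complete set of occurrences
    of each planted pattern.
    """

    planted: Dict[str, List[Tuple[str, int]]]
    report: SiftReport
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "planted": self.planted,
            "report": dict(self.report.to_rows()),
        }
        return json.dumps(payload, sort_keys=True)


def _pattern_positions_in_window(pattern: str, realized: str) -> List[int]:
    """Starts of `pattern`'s occurrences inside a realized planted window."""
    out = []
    for i in range(len(realized) - len(pattern) + 1):
        if realized[i : i + len(pattern)] == pattern:
            out.append(i)
    return out


def _realize(pattern: MotifPattern, rng: np.random.Generator, alphabet: str, probs) -> str:
    return "".join(
        s if s is not None else alphabet[rng.choice(len(alphabet), p=probs)]
        for s in pattern.slots
    )


def make_proteome(
    spec: SyntheticProteomeSpec,
    fasta_path: Optional[Union[str, Path]] = None,
    max_retries: int = 1000,
    short_threshold: int = 100,
) -> Tuple[List[ProteinRecord], GroundTruthManifest]:
    """Generate a proteome with exactly the planted motif occurrences.

    Each planted occurrence is assigned to a random protein; the protein's
    background is redrawn (up to ``max_retries`` times) until scanning
    each distinct planted pattern finds exactly the planted coordinates —
    no stray chance occurrences, no accidental extra anchored windows.
    With the default composition and sizes a retry is rare, so generation
    is effectively linear in total length. Raises ``RuntimeError`` for an
    infeasible plan (e.g. plants that cannot fit).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = "".join(spec.composition.alphabet)
    probs = np.array([spec.composition[a] for a in alphabet])
    probs = probs / probs.sum()

    patterns = {p.pattern: MotifPattern.from_string(p.pattern) for p in spec.plants}

    # Assign each planted occurrence to a protein index. A protein has at
    # most one C terminus, so C-terminal plants draw without replacement.
    total_plants = sum(p.count for p in spec.plants)
    if spec.n_proteins == 0 and total_plants:
        raise RuntimeError("cannot plant motifs into an empty proteome")
    assignments: Dict[int, List[PlantSpec]] = {}
    n_cterm_total = sum(p.count for p in spec.plants if p.placement == "C-terminal")
    if n_cterm_total > spec.n_proteins:
        raise RuntimeError("more C-terminal plants than proteins")
    cterm_slots = list(
        rng.choice(spec.n_proteins, size=n_cterm_total, replace=False)
    ) if n_cterm_total else []
    for plant in spec.plants:
        for _ in range(plant.count):
            if plant.placement == "C-terminal":
                idx = int(cterm_slots.pop())
            else:
                idx = int(rng.integers(spec.n_proteins))
            assignments.setdefault(idx, []).append(plant)

    records: List[ProteinRecord] = []
    planted: Dict[str, List[Tuple[str, int]]] = {p.pattern: [] for p in spec.plants}

    for idx in range(spec.n_proteins):
        pid = f"SYN{idx:05d}"
        plants_here = assignments.get(idx, [])
        n_cterm = sum(1 for p in plants_here if p.placement == "C-terminal")
        if n_cterm > 1:
            raise RuntimeError(f"protein {pid}: more than one C-terminal plant")
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        need = sum(len(p.pattern) for p in plants_here)
        if need + 1 > length:
            raise RuntimeError(f"protein {pid}: plants do not fit in length {length}")

        for attempt in range(max_retries):
            seq = list(alphabet[i] for i in rng.choice(len(alphabet), size=length, p=probs))
            occupied: List[Tuple[int, int]] = []
            placements: List[Tuple[PlantSpec, int, str]] = []
            ok = True
            for plant in plants_here:
                pat = patterns[plant.pattern]
                realized = _realize(pat, rng, alphabet, probs)
                k = len(realized)
                if plant.placement == "C-terminal":
                    start = length - k
                    candidates = [start]
                else:
                    # internal / anchored-window: keep clear of the C terminus
                    candidates = list(rng.permutation(max(0, length - k)))
                placed = False
                for start in candidates:
                    span = (start, start + k)
                    if any(a < span[1] and span[0] < b for a, b in occupied):
                        continue
                    occupied.append(span)
                    placements.append((plant, start, realized))
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                continue
            # A realized plant must contain only the occurrences its own
            # pattern mandates (e.g. the NNI at offset 11 of an anchored
            # window), or the wildcard fill has created a stray hit.
            clean = True
            expected: Dict[str, set] = {p: set() for p in patterns}
            for plant, start, realized in placements:
                skeleton = plant.pattern.replace("x", "X").replace(".", "X")
                for name, pat in patterns.items():
                    allowed = {
                        off
                        for off in range(len(realized) - pat.length + 1)
                        if pat.matches_at(skeleton, off)
                    }
                    if name == plant.pattern:
                        allowed.add(0)
                    actual = {
                        off
                        for off in range(len(realized) - pat.length + 1)
                        if pat.matches_at(realized, off)
                    }
                    if actual != allowed:
                        clean = False
                        break
                    expected[name].update(start + off for off in allowed)
                if not clean:
                    break
            if not clean:
                continue
            for _, start, realized in placements:
                seq[start : start + len(realized)] = realized
            text = "".join(seq)

            rec = ProteinRecord(id=pid, description=pid, sequence=text)
            actual_ok = True
            for name, pat in patterns.items():
                from .motifs import scan_motif

                found = {h.start for h in scan_motif(rec, pat)}
                if found != expected[name]:
                    actual_ok = False
                    break
            if actual_ok:
                records.append(rec)
                for plant, start, realized in placements:
                    planted[plant.pattern].append((pid, int(start)))
                break
        else:
            raise RuntimeError(
                f"protein {pid}: no clean background in {max_retries} attempts"
            )

    for key in planted:
        planted[key].sort()

    motif = patterns.get("NNI", MotifPattern.from_string("NNI"))
    window = next(
        (patterns[p.pattern] for p in spec.plants if p.placement == "anchored-window"),
        None,
    )
    report = build_sift_report(
        records,
        motif=motif,
        sub_patterns=(MotifPattern.from_string("FNNI"), MotifPattern.from_string("EFNNI")),
        short_threshold=short_threshold,
        window_pattern=window,
    )
    manifest = GroundTruthManifest(planted=planted, report=report, seed=spec.seed)
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    return records, manifest


def make_distance_tables(
    base: DistanceTable, jitter_sd: float, n_tables: int, seed: int = 1
) -> List[DistanceTable]:
    """Jittered copies of a base table: base + N(0, sd) per entry, kept positive.

    A draw that would push a distance to zero or below is redrawn
    (truncation), preserving the positive-distance invariant.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    tables = []
    pairs = sorted(base.entries)
    for t in range(n_tables):
        entries = {}
        for p in pairs:
            d = base.entries[p] + rng.normal(0.0, jitter_sd) if jitter_sd > 0 else base.entries[p]
            while d <= 0:
                d = base.entries[p] + rng.normal(0.0, jitter_sd)
            entries[p] = d
        tables.append(DistanceTable(f"{base.peptide_name}_jitter{t}", entries))
    return tables


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Recipe for a preabsorption panel with a planted C-terminal suffix rule.

    Peptides matching ``rule`` at their C terminus are blockers following
    a logistic inhibition curve (per-blocker IC50 in ng/ml and slope);
    non-matching peptides stay at 100% of control. Gaussian replicate
    noise of ``noise_sd`` percentage points is added and the floor is 0.
    Defaults mirror a titration design: doses 0.1-1000 ng/ml, four
    replicates, 5% noise.
    """

    rule: SuffixPattern = field(default_factory=lambda: SuffixPattern.from_string("NNI"))
    peptides: Tuple[Tuple[str, str], ...] = ()  # (code, sequence)
    ic50: Mapping[str, float] = field(default_factory=dict)  # code -> ng/ml
    slope: float = 1.0
    noise_sd: float = 5.0
    n_replicates: int = 4
    concentrations: Tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    control_area: float = 0.04
    seed: int = 1

    def __post_init__(self):
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise ValueError("invalid noise or replicate count")
        if any(v <= 0 for v in self.ic50.values()):
            raise ValueError("IC50s must be positive")


def inhibition_percent(c: float, ic50: float, slope: float) -> float:
    """Noise-free logistic inhibition: 100 / (1 + (c / IC50)^slope)."""
    return 100.0 / (1.0 + (c / ic50) ** slope)


def make_panel_measurements(
    spec: SyntheticPanelSpec,
) -> Tuple[pd.DataFrame, Dict[str, dict]]:
    """Simulate the staining measurements of a titration panel.

    Returns a tidy measurement table (image_id, tissue, peptide_code,
    sequence, concentration_ng_ml, percent_of_control, area_labelled) plus
    a truth record per peptide: whether the planted rule calls it a
    blocker, and its IC50 where applicable. Control rows (peptide-free,
    concentration 0) are included so the percent-of-control pipeline can
    be exercised end to end.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth: Dict[str, dict] = {}
    default_ic50 = 10.0

    for rep in range(spec.n_replicates):
        rows.append(
            {
                "image_id": f"img_CTRL_{rep}",
                "tissue": "synthetic",
                "peptide_code": "NONE",
                "sequence": "",
                "concentration_ng_ml": 0.0,
                "percent_of_control": 100.0,
                "area_labelled": spec.control_area,
            }
        )
    for code, seq in spec.peptides:
        blocks = spec.rule.matches(seq)
        ic50 = spec.ic50.get(code, default_ic50)
        truth[code] = {"sequence": seq, "blocks": blocks, "ic50": ic50 if blocks else None}
        for c in spec.concentrations:
            base = inhibition_percent(c, ic50, spec.slope) if blocks else 100.0
            for rep in range(spec.n_replicates):
                pct = base + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
                pct = max(pct, 0.0)
                rows.append(
                    {
                        "image_id": f"img_{code}_{c:g}_{rep}",
                        "tissue": "synthetic",
                        "peptide_code": code,
                        "sequence": seq,
                        "concentration_ng_ml": c,
                        "percent_of_control": pct,
                        "area_labelled": min(1.0, spec.control_area * pct / 100.0),
                    }
                )
    return pd.DataFrame(rows), truth


def make_images(
    target_fraction: float,
    dims: Tuple[int, int] = (64, 64),
    threshold: int = 128,
    noise_sd: float = 0.0,
    seed: int = 1,
) -> np.ndarray:
    """A grayscale image whose above-threshold area matches the target.

    At zero noise exactly ``round(target * n_pixels)`` pixels exceed the
    threshold; Gaussian intensity noise (clipped to uint8 range) then
    perturbs the realized fraction. Foreground/background placement is a
    seeded pixel permutation, a statistical stand-in for staining texture.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = dims
    n = h * w
    n_fg = round(target_fraction * n)
    flat = np.full(n, threshold - 64 if threshold >= 64 else 0, dtype=float)
    flat[:n_fg] = min(threshold + 64, 255)
    rng.shuffle(flat)
    if noise_sd > 0:
        flat = flat + rng.normal(0.0, noise_sd, size=n)
    return np.clip(np.round(flat), 0, 255).astype(np.uint8).reshape(h, w)
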