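"""Bundled reference data for the EPL001 / G530 epitope-mapping study.

The anti-EPL001 antibody G530 was raised against the Edman-derived 14-mer
EPL001 (MKPLTGKVKEFNNI). The study's peptide preabsorption panel, the
published per-protein odds for the cross-phylum sequence matches, the dose
levels of the competition experiments and the printed subsets of the
interatomic-distance measurements are collected here so that the analyses
can be rerun without any external download. Proteome-census counts
(motif-ome sizes etc.) are database-snapshot dependent and deliberately
not bundled as assertions.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .conformers import AtomSelection
from .preabsorption import PanelEntry

#: The Edman 14-mer the antibody was raised against.
EPL001_SEQUENCE = "MKPLTGKVKEFNNI"

#: EPL001 minus its C-terminal NNI: the 11-residue anagram reference multiset.
EPL001_MINUS_NNI = "MKPLTGKVKEF"

#: Distinct residues of EPL001-minus-NNI (the Method-of-Exclusion allowed set).
ALLOWED_RESIDUES = "MKPLTGVEF"

#: Canonical residues absent from EPL001 (the Method-of-Exclusion excluded set).
EXCLUDED_RESIDUES = "ARNDCQHISWY"

#: Published per-protein 5-aa chance-match odds (reciprocals), taken as inputs:
#: theoretical (619-aa protein vs fly ID peptide; 1220-aa vs rat ID peptide)
#: and empirical (UniRef50 census figures).
THEORETICAL_ODDS = (5247, 2636)
EMPIRICAL_ODDS = (6201, 4378)

#: Competing-peptide concentrations of the dose-response study, ng/ml.
DOSE_CONCENTRATIONS = (0.1, 1.0, 10.0, 100.0, 1000.0)


def g530_panel() -> List[PanelEntry]:
    """The published preabsorption panel: peptide, sequence, blockade call.

    Alanine-substituted FNNI variants carry ``variant_of="FNNI"`` and are
    analysed by the substitution scan rather than the suffix search; ANNI
    blocked at the highest concentration only.
    """
    rows: List[Tuple[str, str, str, str]] = [
        ("EPL001", "MKPLTGKVKEFNNI", "yes", ""),
        ("rSgII-20", "DEDDVYKTNNIAYEDVVGGE", "no", ""),
        ("fly-20", "KRSKEQKKNNISHHNYKLKN", "no", ""),
        ("EPL122", "MLKTGEKPVKFNNIKGLEQF", "no", ""),
        ("EPL142", "MLKTGEKPVKFNNI", "yes", ""),
        ("EPL143", "MLKTGEKPVFKNNI", "yes", ""),
        ("EPL801", "MKPVFNNI", "yes", ""),
        ("EPL373", "MLKTGEKPN", "no", ""),
        ("EPL601", "MKPVFN", "no", ""),
        ("EPL030", "KLKMNGKNIEPVFT", "no", ""),
        ("EPL536", "KEFNNI", "yes", ""),
        ("EPL545", "EFNNI", "yes", ""),
        ("GKV", "GKV", "no", ""),
        ("KVK", "KVK", "no", ""),
        ("VKE", "VKE", "no", ""),
        ("KEF", "KEF", "no", ""),
        ("EFN", "EFN", "no", ""),
        ("FNN", "FNN", "no", ""),
        ("NNI", "NNI", "yes", ""),
        ("FNNI", "FNNI", "yes", ""),
        ("FNNA", "FNNA", "yes", "FNNI"),
        ("FNAI", "FNAI", "yes", "FNNI"),
        ("FANI", "FANI", "yes", "FNNI"),
        ("ANNI", "ANNI", "highest-conc-only", "FNNI"),
    ]
    return [
        PanelEntry(code, seq, blocks, variant_of=var or None)
        for code, seq, blocks, var in rows
    ]


#: Dose-response outcome of the alanine-substitution titration: did the
#: tetramer return a concentration-response (blockade) curve?
FNNI_SUBSTITUTION_CURVES: Dict[str, bool] = {
    "FNNI": True,
    "FNAI": True,
    "FANI": True,
    "FNNA": False,
    "ANNI": False,
}

#: Published (concentration ng/ml -> (mean percent-of-control, SEM, n))
#: for preabsorption by EPL001 alone.
EPL001_DOSE_RESPONSE: Dict[float, Tuple[float, float, int]] = {
    0.1: (0.56, 0.56, 4),
    1.0: (0.30, 0.30, 4),
    10.0: (0.0, 0.0, 4),
    100.0: (0.09, 0.05, 4),
    1000.0: (0.0, 0.0, 4),
}

#: Published single-dose summaries (mean, SEM, n) at 100 ng/ml and 10 ug/ml.
KEFNNI_SUMMARIES = {100.0: (29.53, 9.69, 8), 10000.0: (4.7, 2.4, 3)}
MKPVFNNI_SUMMARIES = {100.0: (44.40, 11.85, 8), 10000.0: (3.92, 1.97, 3)}

#: FNNI asymptotic staining (percent of control) at the top doses.
FNNI_ASYMPTOTE = {100.0: 2.7, 1000.0: 3.5}


def kefnni_atom_selections() -> List[AtomSelection]:
    """The eleven labelled atoms (a-k) within EPL001's KEFNNI used for
    interatomic distance measurements."""
    rows = [
        ("a", "K9", "nitrogen in the side-chain"),
        ("b", "E10", "delta carbon"),
        ("c", "E10", "hydroxyl oxygen in the side-chain"),
        ("d", "F11", "beta carbon"),
        ("e", "F11", "gamma carbon"),
        ("f", "I14", "peptide bond carbon"),
        ("g", "I14", "delta carbon"),
        ("h", "N13", "gamma carbon"),
        ("i", "N13", "nitrogen of the side-chain"),
        ("j", "N12", "peptide bond carbon"),
        ("k", "N12", "nitrogen of side-chain"),
    ]
    return [AtomSelection(label, tag, desc) for label, tag, desc in rows]


#: Published F-to-I interatomic distances (Angstrom) within each model:
#: the four pairs d-f, d-g, e-f, e-g, printed for the FNNI as embedded in
#: EPL001, as embedded in MKPVFNNI (EPL801), and in free KEFNNI.
F_TO_I_DISTANCES: Dict[str, Dict[str, float]] = {
    "EPL001": {"d-f": 6.79, "d-g": 5.49, "e-f": 7.45, "e-g": 8.45},
    "EPL801": {"d-f": 6.34, "d-g": 7.40, "e-f": 6.90, "e-g": 8.96},
    "KEFNNI": {"d-f": 10.57, "d-g": 13.56, "e-f": 12.21, "e-g": 14.01},
}

#: Published whole-table comparison statistics (observed peptide ->
#: (chi-squared vs EPL001-embedded distances, dof)). The underlying full
#: tables are an external deposit and not bundled.
PUBLISHED_CHI_SQUARED = {
    "KEFNNI": (111.31, 45),
    "EFNNI": (23.67, 35),
    "FNNI": (4.54, 19),
    "NNI": (4.36, 7),
    "FNNI-in-MKPVFNNI": (4.33, 19),
}

#: Published big-difference proportions ((O-E)^2 > 10) per free peptide.
PUBLISHED_BIG_DIFF_PERCENT = {"KEFNNI": 39.0, "EFNNI": 11.0, "FNNI": 5.0, "NNI": 25.0}

#: Published ovine proteome census figures (TrEMBL-snapshot dependent).
OVINE_CENSUS = {
    "proteome_size": 26443,
    "motif_ome_size": 1100,
    "total_hits": 1181,
    "terminal_hits": 3,
    "sub_pattern_FNNI": 42,
    "sub_pattern_EFNNI": 7,
    "short_protein_count": 17,
    "methionine_pool": 22207,
    "anchored_window_count": 25,
    "exclusion_survivor_count": 38,
}
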