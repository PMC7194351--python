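"""Run configuration shared by the command-line subcommands.

A flat YAML key-value file supplies defaults; command-line flags override
file values (flag > file > built-in default). Every constant of the
analysis — motif strings, the allowed/excluded residue sets of the Method
of Exclusion, the short-protein threshold, the big-difference threshold,
the verdict confidence — lives here so a run is fully described by its
config plus its seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .records import CANONICAL_RESIDUES

__all__ = ["RunConfig", "load_config", "write_run_manifest"]


@dataclass(frozen=True)
class RunConfig:
    motif: str = "NNI"
    sub_patterns: str = "FNNI,EFNNI"
    window: str = "MxxxxxxxxxxNNI"
    allowed_residues: str = "MKPLTGVEF"
    excluded_residues: str = "ARNDCQHISWY"
    short_threshold: int = 100
    big_diff_threshold: float = 10.0
    confidence: float = 0.995
    t_test_variant: str = "pooled"
    max_suffix_len: int = 6
    seed: int = 1
    out_dir: str = "epimap_out"

    def validate(self) -> None:
        problems = []
        for name in ("allowed_residues", "excluded_residues"):
            value = getattr(self, name)
            bad = sorted(set(value.upper()) - CANONICAL_RESIDUES)
            if bad:
                problems.append(f"{name}: non-canonical letter(s) {bad}")
        if self.short_threshold <= 0:
            problems.append("short_threshold: must be positive")
        if self.big_diff_threshold <= 0:
            problems.append("big_diff_threshold: must be positive")
        if not 0 < self.confidence < 1:
            problems.append("confidence: must lie in (0, 1)")
        if self.t_test_variant not in ("pooled", "welch"):
            problems.append("t_test_variant: must be 'pooled' or 'welch'")
        if self.max_suffix_len < 1:
            problems.append("max_suffix_len: must be >= 1")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


def load_config(
    path: Optional[Union[str, Path]] = None, overrides: Optional[Dict[str, Any]] = None
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus flag overrides."""
    values: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a flat key-value mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = sorted(set(loaded) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**values)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def write_run_manifest(
    cfg: RunConfig, out_dir: Union[str, Path], subcommand: str, inputs: Dict[str, Any]
) -> Path:
    """Record inputs, parameters, package version and seed next to results."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": asdict(cfg),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
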