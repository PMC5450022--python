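"""Run configuration: one serializable object holding every threshold.

The config round-trips losslessly through YAML; unknown keys are
rejected so typos cannot silently fall back to defaults. The SHA-256
hash of the canonical serialization is stamped into every output file,
making reruns bit-reproducible and attributable.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    seed: int = 0
    schema_version: str = SCHEMA_VERSION

    # synthetic movie settings (None → an input movie is loaded from paths)
    movie: Optional[dict[str, Any]] = None
    # morphology thresholds (ClassThresholds field overrides)
    thresholds: dict[str, Any] = field(default_factory=dict)
    # tracking: gate (px), division_radius (px or null for auto)
    tracking: dict[str, Any] = field(default_factory=dict)
    # kinetics: persistence, mitosis_threshold, frames_per_day, grid_k
    kinetics: dict[str, Any] = field(default_factory=dict)
    # synthetic compendium settings (CompendiumConfig overrides)
    compendium: Optional[dict[str, Any]] = None
    # meta-analysis: fold_threshold, strong_quantile
    meta: dict[str, Any] = field(default_factory=dict)
    # input/output paths
    paths: dict[str, Any] = field(default_factory=dict)

    _ALLOWED_SUBKEYS = {
        "thresholds": {"lw_neuron", "min_neurites", "lw_shrunken", "nc_shrunken",
                       "nc_mef", "area_small", "area_large", "min_neurite_len"},
        "tracking": {"gate", "division_radius"},
        "kinetics": {"persistence", "mitosis_threshold", "frames_per_day", "grid_k",
                     "recent_window"},
        "meta": {"fold_threshold", "strong_quantile"},
    }

    def validate(self) -> None:
        for section, allowed in self._ALLOWED_SUBKEYS.items():
            got = set(getattr(self, section) or {})
            unknown = got - allowed
            if unknown:
                raise ValueError(f"unknown keys in {section}: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(self.canonical())

    def canonical(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def header(self) -> str:
        return f"config_hash={self.config_hash()} seed={self.seed}"
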