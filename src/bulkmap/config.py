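"""Pipeline configuration: every tunable of the analysis in one record.

Each parameter carries a provenance tag: ``study`` for values the emulated
study states (window/step size, permutation count, confidence level, marker
filters, DEG thresholds), ``package`` for values the study leaves open
(minimum markers per window, depth-clause pool scope, tie-breaks, seed).
Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["PipelineConfig", "PARAM_PROVENANCE"]

PARAM_PROVENANCE = {
    "window_bp": "study",
    "step_bp": "study",
    "n_perm": "study",
    "level": "study",
    "index_min": "study",
    "depth_min": "study",
    "fpkm_min": "study",
    "lfc_min": "study",
    "q_max": "study",
    "min_markers": "package",
    "depth_rule": "package",
    "bulk_size": "study",
    "seed": "package",
}


@dataclass
class PipelineConfig:
    window_bp: int = 20_000
    step_bp: int = 2_000
    n_perm: int = 1000
    level: float = 0.95
    index_min: float = 0.3
    depth_min: int = 7
    fpkm_min: float = 1.0
    lfc_min: float = 1.0
    q_max: float = 0.05
    min_markers: int = 3
    depth_rule: str = "either"
    bulk_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if not 0 < self.level <= 1:
            raise ValueError("level must be in (0, 1]")
        if self.depth_rule not in {"either", "both"}:
            raise ValueError("depth_rule must be 'either' or 'both'")
        for name in ("window_bp", "step_bp", "n_perm", "min_markers", "bulk_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.q_max <= 0 or self.fpkm_min < 0 or self.lfc_min < 0:
            raise ValueError("q_max must be > 0; fpkm_min/lfc_min must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        return cls.from_dict(data or {})

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            if str(path).endswith((".yml", ".yaml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
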