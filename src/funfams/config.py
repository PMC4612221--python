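"""Run-wide configuration: every pipeline threshold with its default.

A single YAML file can override any default; unknown keys are rejected so
typos fail loudly. CLI flags override YAML values.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import UsageError


@dataclass
class RunConfig:
    seed: int = 0
    identity: float = 0.90                # preclustering identity
    fragment_fraction: float = 0.8        # min length / average length
    conservation_threshold: float = 0.7   # highly-conserved cutoff
    dops_cutoff: float = 70.0             # D_f informativeness cutoff
    gap_column_fraction: float = 0.5      # column counts as gapped at >= this
    min_nongap_fraction: float = 0.5      # GroupSim column defined at >= this
    fc_rule: str = "strict_gap"           # "as_printed" | "strict_gap"
    cut_strategy: str = "subtree"         # "subtree" | "first_coherent"
    matrix: str = "BLOSUM62"
    weighting: str = "henikoff"           # "none" | "henikoff"
    assign_mode: str = "best_hit"         # "best_hit" | "all_above_threshold"

    def __post_init__(self):
        checks = {
            "identity": (0.0, 1.0),
            "fragment_fraction": (0.0, 1.0),
            "conservation_threshold": (0.0, 1.0),
            "dops_cutoff": (0.0, 100.0),
            "gap_column_fraction": (0.0, 1.0),
            "min_nongap_fraction": (0.0, 1.0),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise UsageError(f"{name}={v} outside [{lo}, {hi}]")
        if self.fc_rule not in ("as_printed", "strict_gap"):
            raise UsageError(f"unknown fc_rule {self.fc_rule!r}")
        if self.cut_strategy not in ("subtree", "first_coherent"):
            raise UsageError(f"unknown cut_strategy {self.cut_strategy!r}")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
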