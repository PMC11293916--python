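"""Run-time configuration shared by the measurement and classification layers."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Tunable thresholds of the measurement -> classification pipeline.

    All angles are degrees.  ``structural_threshold``, ``modifier_low`` and
    ``modifier_high`` are clinical rule switch points (a curve is structural
    only if its side-bending residual stays strictly above 25 deg; T5-T12
    kyphosis strictly below 10 deg is hypokyphotic "-", strictly above 40 deg
    hyperkyphotic "+").  The remaining knobs are detection plumbing.
    """

    min_prominence: float = 5.0        # extremum prominence floor for peak/trough detection
    min_cobb: float = 10.0             # smallest peak-trough difference kept as a curve
    structural_threshold: float = 25.0
    modifier_low: float = 10.0
    modifier_high: float = 40.0
    lock_end_vertebrae_on_bending: bool = False
    canonical_lenke_sagittal_criteria: bool = False
    smoothing_window: int = 1          # centered moving average; 1 = off
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_prominence", "min_cobb", "structural_threshold",
                     "modifier_low", "modifier_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.modifier_low >= self.modifier_high:
            raise ValueError("modifier_low must be < modifier_high")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 1")

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **{k: v for k, v in overrides.items() if v is not None})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a TOML or YAML file (unknown keys rejected)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
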