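"""Validated pipeline configuration with YAML/JSON loading."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the measurement and statistics pipeline.

    Units: ``um_per_px`` µm per pixel; contrasts on the 8-bit intensity
    scale; ``elimination_alpha`` the backward-elimination significance level.
    """

    um_per_px: float = 1.0
    run_length: int = 3
    min_contrast: float = 10.0
    min_separation_um: float = 5.0
    strict_protocol: bool = True
    t_test_mode: str = "auto"  # pooled | welch | auto
    elimination_alpha: float = 0.05
    pi_mode: str = "exact"  # exact | paper
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.um_per_px > 0):
            raise ConfigError("um_per_px must be positive")
        if self.run_length < 2:
            raise ConfigError("run_length must be >= 2")
        if not (self.min_contrast > 0):
            raise ConfigError("min_contrast must be positive")
        if not (self.min_separation_um > 0):
            raise ConfigError("min_separation_um must be positive")
        if self.t_test_mode not in ("pooled", "welch", "auto"):
            raise ConfigError(f"unknown t_test_mode {self.t_test_mode!r}")
        if not (0 < self.elimination_alpha < 1):
            raise ConfigError("elimination_alpha must be in (0, 1)")
        if self.pi_mode not in ("exact", "paper"):
            raise ConfigError(f"unknown pi_mode {self.pi_mode!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)
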