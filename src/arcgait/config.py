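"""Run configuration: one validated YAML-backed object wiring profile,
constants, detector gates, phase windows, axis mapping and mode."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .events import DEFAULT_AXES
from .features import PhaseWindows
from .profiles import AnthropometricProfile, ModelConstants


@dataclass
class RunConfig:
    """Validated pipeline configuration.  Unknown keys in a YAML file are
    rejected; every stochastic run records its seed in its outputs."""

    profile: AnthropometricProfile = field(
        default_factory=lambda: AnthropometricProfile(L=0.9, f=0.25)
    )
    constants: ModelConstants = field(default_factory=ModelConstants)
    min_separation_s: float = 0.4
    prominence_m: float = 0.003
    cycle_bounds_s: tuple = (0.4, 3.0)
    smoothing_method: str = "lowpass"
    smoothing_cutoff_hz: float = 6.0
    windows: PhaseWindows = field(default_factory=PhaseWindows)
    axes: dict = field(default_factory=lambda: dict(DEFAULT_AXES))
    mode: str = "overground"
    belt_speed: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("overground", "treadmill"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.min_separation_s <= 0 or self.prominence_m < 0:
            raise ConfigError("detector gates must be positive")
        lo, hi = self.cycle_bounds_s
        if not 0 < lo < hi:
            raise ConfigError("cycle bounds must satisfy 0 < lo < hi")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs = dict(raw)
        if "profile" in kwargs:
            kwargs["profile"] = AnthropometricProfile(**kwargs["profile"])
        if "constants" in kwargs:
            kwargs["constants"] = ModelConstants(**kwargs["constants"])
        if "windows" in kwargs:
            kwargs["windows"] = PhaseWindows(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["windows"].items()}
            )
        if "cycle_bounds_s" in kwargs:
            kwargs["cycle_bounds_s"] = tuple(kwargs["cycle_bounds_s"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["cycle_bounds_s"] = list(self.cycle_bounds_s)
        data["windows"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self.windows).items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
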