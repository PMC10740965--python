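"""Subject geometry and physical constants.

The model reduces a walker to a 2-link leg (thigh ``l1``, shank-to-rocker
segment ``l2``) standing on a circular-arc ("rocker") foot of radius ``r``,
with total leg length ``L = l1 + l2`` and anatomical foot length ``f``.
Upright, the hip height is ``l1 + (l2 - r) + r = L``, which is why the
two segment lengths must sum to the leg length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import GeometryError

#: standard gravity, m/s^2
G = 9.81

#: double-support fraction of the gait cycle in normal stable walking
DEFAULT_XI = 0.10


@dataclass(frozen=True)
class AnthropometricProfile:
    """Per-subject geometry of the 2-DOF arced-foot pendulum.

    Parameters
    ----------
    L : float
        Leg length (hip to ground, upright), m.
    f : float
        Anatomical foot length, m.
    l1, l2 : float, optional
        Thigh length and shank-to-rocker-centre length, m. Must satisfy
        ``l1 + l2 == L``; both default to ``L/2``.
    r : float
        Rocker (arced foot) radius, m. Must be smaller than ``L``.
    m : float
        Body mass, kg (used only by the moment-balance diagnostic).
    """

    L: float
    f: float
    l1: float | None = None
    l2: float | None = None
    r: float = 0.05
    m: float = 70.0

    def __post_init__(self) -> None:
        if self.l1 is None:
            object.__setattr__(self, "l1", self.L / 2.0)
        if self.l2 is None:
            object.__setattr__(self, "l2", self.L - self.l1)
        for name in ("L", "f", "l1", "l2", "m"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.r < 0:
            raise GeometryError("rocker radius r must be non-negative")
        if abs(self.l1 + self.l2 - self.L) > 1e-9:
            raise GeometryError(
                f"l1 + l2 = {self.l1 + self.l2!r} must equal leg length L = {self.L!r}"
            )
        if self.r >= self.L:
            raise GeometryError("rocker radius r must be smaller than leg length L")
        if self.f >= self.L:
            warnings.warn(
                "foot length f >= leg length L is anatomically implausible",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ModelConstants:
    """Environment/gait-cycle constants: gravity ``g`` and the
    double-support fraction ``xi`` of the gait cycle (~0.10 in normal
    stable walking)."""

    g: float = G
    xi: float = DEFAULT_XI

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise GeometryError("g must be strictly positive")
        if not (0.0 <= self.xi < 0.5):
            raise GeometryError("double-support fraction xi must lie in [0, 0.5)")


#: profile matching the validation cohort (adults ~1.70 m tall):
#: leg 0.9 m, foot 0.25 m, rocker 0.05 m, mass 70 kg.
DEFAULT_PROFILE = AnthropometricProfile(L=0.9, f=0.25, r=0.05, m=70.0)

DEFAULT_CONSTANTS = ModelConstants()
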