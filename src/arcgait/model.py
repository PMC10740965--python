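"""Closed-form kinematics of the 2-DOF arced-foot inverted-pendulum gait model.

The central quantity is the *roll factor* rho, the ratio of the virtual
(rocker-extended) leg to the real leg.  For a rocker of radius ``r`` under a
leg of length ``L`` (Gard's 1-DOF model) it is ``rho_G = 1/(1 - r/L)``; in
the 2-DOF model with a knee it is recovered purely from spatiotemporal
gait data as ``rho = 1 + f/(Sl - f)`` with foot length ``f`` and step
length ``Sl``.  Every other kinematic parameter of steady walking — step
length, cadence, gait speed, vertical excursion of the centre of mass —
is then a function of rho alone once ``L`` and ``f`` are fixed:

    Sl   = rho*f/(rho - 1)
    NC   = (1 - 2*xi)*sqrt(2 - rho)/T0          (steps/s; *60 for steps/min)
    V    = (1 - 2*xi)*(f/T0)*sqrt(2 - rho)*rho/(rho - 1)
    dh   = rho*f**2 / (8*L*(rho - 1)**2)

with ``T0 = sqrt(L/g)`` the inherent pendulum period (this convention
carries no 2*pi factor) and ``xi`` the double-support fraction of the gait
cycle.  Efficient pendular walking requires ``1 < rho < 2``; outside that
band the model refuses to evaluate the pendular quantities (see the
:mod:`arcgait.recognition` module for the band semantics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SingularStepError
from .profiles import DEFAULT_CONSTANTS, AnthropometricProfile, ModelConstants

__all__ = [
    "GaitParameters",
    "roll_factor_gard",
    "roll_factor_from_step",
    "step_length_from_rho",
    "inherent_period",
    "natural_frequency",
    "swing_period",
    "cadence_per_second",
    "cadence",
    "gait_speed",
    "vertical_excursion",
    "predict_gait",
]

_SL_SINGULARITY = 1e-12  # |Sl - f| below this is a singular step


def _ret(x):
    """Return a python float for 0-d results, ndarray otherwise."""
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


def roll_factor_gard(r, L):
    """Roll factor of the 1-DOF rocker-based pendulum: ``1/(1 - r/L)``.

    ``r`` is the rocker radius and ``L`` the leg length (m).  Always >= 1;
    ``r -> L`` is singular (the virtual leg diverges).
    """
    r = np.asarray(r, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise DomainError("leg length L must be strictly positive")
    if np.any(r < 0) or np.any(r >= L):
        raise DomainError("rocker radius must satisfy 0 <= r < L")
    return _ret(1.0 / (1.0 - r / L))


def roll_factor_from_step(Sl, f):
    """Roll factor from spatiotemporal data: ``rho = 1 + f/(Sl - f)``.

    ``Sl`` is the step length and ``f`` the foot length (m).  The result
    falls in (1, 2) iff ``Sl > 2f``, above 2 iff ``f < Sl < 2f``, and
    below 1 (possibly negative) iff ``Sl < f`` — the walking-style bands.

    Raises
    ------
    SingularStepError
        If ``Sl == f`` within 1e-12 m (pole of the map).
    """
    Sl = np.asarray(Sl, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("foot length f must be strictly positive")
    if np.any(Sl < 0):
        raise DomainError("step length Sl must be non-negative")
    if np.any(np.abs(Sl - f) < _SL_SINGULARITY):
        raise SingularStepError("step length equals foot length: roll factor singular")
    return _ret(1.0 + f / (Sl - f))


def step_length_from_rho(rho, f):
    """Step length from the roll factor: ``Sl = rho*f/(rho - 1)``.

    Exact inverse of :func:`roll_factor_from_step` on the forward branch
    ``rho > 1``; diverges as ``rho -> 1+``.
    """
    rho = np.asarray(rho, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("foot length f must be strictly positive")
    if np.any(rho <= 1.0):
        raise DomainError("step-length map requires rho > 1")
    return _ret(rho * f / (rho - 1.0))


def inherent_period(L, g=DEFAULT_CONSTANTS.g):
    """Inherent pendulum period ``T0 = sqrt(L/g)`` (s; no 2*pi factor)."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0) or g <= 0:
        raise DomainError("L and g must be strictly positive")
    return _ret(np.sqrt(L / g))


def _check_pendular(rho, lo_open: bool) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any(rho >= 2.0):
        raise DomainError("rho >= 2: outside the pendular band (non-pendular regime)")
    lo_bad = rho <= 1.0 if lo_open else rho < 1.0
    if np.any(lo_bad):
        raise DomainError("rho below the pendular band")
    return rho


def natural_frequency(rho, L, g=DEFAULT_CONSTANTS.g):
    """Natural frequency ``omega = sqrt((2 - rho)*g/L)`` (rad/s), 1 <= rho < 2."""
    rho = _check_pendular(rho, lo_open=False)
    return _ret(np.sqrt((2.0 - rho) * g / np.asarray(L, dtype=float)))


def swing_period(rho, L, g=DEFAULT_CONSTANTS.g):
    """Swing period ``T = T0/sqrt(2 - rho) = 1/omega`` (s).

    Follows the model's literal convention ``T = 1/omega`` (no 2*pi);
    at ``rho = 1`` it reduces to the inherent period ``T0``.
    """
    rho = _check_pendular(rho, lo_open=False)
    return _ret(inherent_period(L, g) / np.sqrt(2.0 - rho))


def cadence_per_second(rho, L, xi=DEFAULT_CONSTANTS.xi, g=DEFAULT_CONSTANTS.g):
    """Step rate ``(1 - 2*xi)*sqrt(2 - rho)/T0`` in steps/s.

    The double-support fraction ``xi`` scales the whole expression, so a
    cycle entirely in double support (``xi -> 0.5``) yields zero cadence.
    Strictly decreasing in both ``rho`` and ``xi``.
    """
    rho = _check_pendular(rho, lo_open=True)
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0) or np.any(xi >= 0.5):
        raise DomainError("double-support fraction xi must lie in [0, 0.5)")
    return _ret((1.0 - 2.0 * xi) * np.sqrt(2.0 - rho) / inherent_period(L, g))


def cadence(rho, L, xi=DEFAULT_CONSTANTS.xi, g=DEFAULT_CONSTANTS.g):
    """Cadence in steps/min: ``60 *`` :func:`cadence_per_second`."""
    return _ret(60.0 * np.asarray(cadence_per_second(rho, L, xi, g)))


def gait_speed(rho, f, L, xi=DEFAULT_CONSTANTS.xi, g=DEFAULT_CONSTANTS.g):
    """Gait speed ``V = (1 - 2*xi)*(f/T0)*sqrt(2 - rho)*rho/(rho - 1)`` (m/s).

    Algebraically identical to step rate x step length; implemented from
    its own closed form so the identity is a genuine cross-check.
    """
    rho = _check_pendular(rho, lo_open=True)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("foot length f must be strictly positive")
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0) or np.any(xi >= 0.5):
        raise DomainError("double-support fraction xi must lie in [0, 0.5)")
    T0 = inherent_period(L, g)
    return _ret((1.0 - 2.0 * xi) * (f / T0) * np.sqrt(2.0 - rho) * rho / (rho - 1.0))


def vertical_excursion(rho, f, L):
    """Vertical excursion of the COM, ``dh = rho*f**2/(8*L*(rho - 1)**2)`` (m).

    Small-angle closed form; strictly decreasing in rho on (1, 2) —
    longer steps (smaller rho) raise and drop the COM more.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 1.0):
        raise DomainError("vertical excursion requires rho > 1")
    f = np.asarray(f, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(f <= 0) or np.any(L <= 0):
        raise DomainError("f and L must be strictly positive")
    return _ret(rho * f**2 / (8.0 * L * (rho - 1.0) ** 2))


@dataclass(frozen=True)
class GaitParameters:
    """Bundle of model kinematics for one condition (one rho).

    Fields: roll factor ``rho``; step length ``step_length`` (m); cadence
    ``cadence`` (steps/min) and ``cadence_per_s`` (steps/s); gait speed
    ``speed`` (m/s); COM vertical excursion ``com_excursion`` (m); swing
    period ``swing_period`` (s); inherent period ``inherent_period`` (s);
    natural frequency ``natural_frequency`` (rad/s).
    """

    rho: float
    step_length: float
    cadence: float
    cadence_per_s: float
    speed: float
    com_excursion: float
    swing_period: float
    inherent_period: float
    natural_frequency: float

    def __post_init__(self) -> None:
        if not (1.0 < self.rho < 2.0):
            raise DomainError("GaitParameters requires 1 < rho < 2")
        if self.com_excursion < 0:
            raise DomainError("com_excursion must be non-negative")
        v_id = self.cadence / 60.0 * self.step_length
        if abs(self.speed - v_id) > 1e-10 * max(abs(self.speed), 1e-300):
            raise DomainError("speed != cadence/60 * step_length: inconsistent bundle")

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "step_length_m": self.step_length,
            "cadence_steps_per_min": self.cadence,
            "cadence_steps_per_s": self.cadence_per_s,
            "speed_m_per_s": self.speed,
            "com_excursion_m": self.com_excursion,
            "swing_period_s": self.swing_period,
            "inherent_period_s": self.inherent_period,
            "natural_frequency_rad_per_s": self.natural_frequency,
        }


def predict_gait(
    rho: float,
    profile: AnthropometricProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> GaitParameters:
    """All kinematic gait parameters for a roll factor in the pendular band."""
    rho = float(rho)
    if not (1.0 < rho < 2.0):
        raise DomainError("predict_gait requires 1 < rho < 2")
    L, f, g, xi = profile.L, profile.f, constants.g, constants.xi
    return GaitParameters(
        rho=rho,
        step_length=step_length_from_rho(rho, f),
        cadence=cadence(rho, L, xi, g),
        cadence_per_s=cadence_per_second(rho, L, xi, g),
        speed=gait_speed(rho, f, L, xi, g),
        com_excursion=vertical_excursion(rho, f, L),
        swing_period=swing_period(rho, L, g),
        inherent_period=inherent_period(L, g),
        natural_frequency=natural_frequency(rho, L, g),
    )
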