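"""Single-support dynamics of the 2-DOF arced-foot inverted pendulum.

During single support the stance leg pivots about the ground contact point
of the rocker.  With the hip angle ``theta_r`` measured from vertical and
the knee angle ``beta_r`` held small, the moment balance about the contact
point linearizes to

    theta_ddot = (g/L) * (2 - rho) * theta_r

For ``rho < 2`` the coefficient is positive, so the upright equilibrium is
hyperbolic (cosh/sinh solutions) — the standard behaviour of an inverted
pendulum falling through mid-stance.  The model nevertheless defines a
"natural frequency" ``omega = sqrt((g/L)(2 - rho))`` and swing period
``T = 1/omega`` from the magnitude of this coefficient; we implement the
equation of motion literally and keep both conventions side by side.

The COM height is the exact two-link geometry

    h = l1*cos(theta) + (l2 - r)*cos(theta - beta) + r

whose droop ``L - h`` is the geometric counterpart of the closed-form
excursion ``rho*f**2/(8*L*(rho-1)**2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GeometryError, IntegrationError
from .profiles import DEFAULT_CONSTANTS, AnthropometricProfile, ModelConstants

__all__ = [
    "PendulumState",
    "ContactGeometry",
    "COMTrajectory",
    "contact_distance",
    "geometric_offsets",
    "linearized_acceleration",
    "simulate_single_support",
    "com_height",
    "vertical_excursion_geometric",
    "moment_balance_residual",
]


@dataclass(frozen=True)
class PendulumState:
    """Instantaneous single-support state: hip angle ``theta_r`` (rad,
    from vertical), knee angle ``beta_r`` (rad), hip angular velocity
    ``theta_dot`` (rad/s), time ``t`` (s)."""

    theta_r: float
    beta_r: float = 0.0
    theta_dot: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.theta_r, self.beta_r, self.theta_dot, self.t)
        if not all(math.isfinite(v) for v in vals):
            raise IntegrationError("non-finite pendulum state")
        if abs(self.theta_r) >= math.pi / 2:
            raise DomainError("|theta_r| must be < pi/2 during single support")


@dataclass(frozen=True)
class ContactGeometry:
    """Linearized geometry about the ground contact point Q: the angle
    ``theta_r_prime`` of the hip-to-contact line PQ from vertical, the
    distance ``Liv`` between P and Q, and the horizontal/vertical COM
    offsets from the arc centre, ``x_off = xcom - xa`` and
    ``y_off = ycom - ya``."""

    theta_r_prime: float
    Liv: float
    x_off: float
    y_off: float

    def __post_init__(self) -> None:
        if not self.Liv > 0:
            raise GeometryError("contact distance Liv must be strictly positive")


@dataclass(frozen=True)
class COMTrajectory:
    """Sampled single-support trajectory: times ``t`` (s), hip angles
    ``theta`` (rad), hip angular velocities ``theta_dot`` (rad/s) and COM
    heights ``h`` (m); ``dh_peak`` is the largest COM droop max(L - h)."""

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    h: np.ndarray
    L: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise IntegrationError("trajectory time samples must strictly increase")
        if np.any(self.h > self.L + 1e-9):
            raise IntegrationError("COM height exceeds leg length")

    @property
    def dh_peak(self) -> float:
        return float(np.max(self.L - self.h))


def contact_distance(profile: AnthropometricProfile) -> float:
    """Default hip-to-contact distance ``Liv = L - r``: for a rocker of
    radius r near upright the contact point sits one radius below the
    ankle-rocker centre line."""
    return profile.L - profile.r


def geometric_offsets(
    state: PendulumState,
    profile: AnthropometricProfile,
    rho: float,
    Liv: float | None = None,
) -> ContactGeometry:
    """Linearized COM offsets from the contact point.

    Uses the small-angle relations

        theta_r' = (L*rho/Liv)*theta_r + ((l2 - r)/Liv)*beta_r
        x_off    = -(Liv*theta_r' - r*(theta_r - beta_r))
        y_off    = Liv * cos(theta_r') ~= Liv

    so that a COM ahead of the contact (theta_r > 0, beta_r = 0) has a
    negative ``x_off`` under this sign convention.
    """
    if rho <= 1.0:
        raise DomainError("geometric offsets require rho > 1")
    if Liv is None:
        Liv = contact_distance(profile)
    if Liv <= 0:
        raise GeometryError("contact distance Liv must be strictly positive")
    L, l2, r = profile.L, profile.l2, profile.r
    theta_p = (L * rho / Liv) * state.theta_r + ((l2 - r) / Liv) * state.beta_r
    x_off = -(Liv * theta_p - r * (state.theta_r - state.beta_r))
    return ContactGeometry(theta_r_prime=theta_p, Liv=Liv, x_off=x_off, y_off=Liv)


def linearized_acceleration(theta_r, rho, L, g=DEFAULT_CONSTANTS.g):
    """Linearized hip-angle acceleration ``(g/L)*(2 - rho)*theta_r`` (rad/s^2)."""
    theta_r = np.asarray(theta_r, dtype=float)
    out = (g / L) * (2.0 - rho) * theta_r
    return float(out) if out.ndim == 0 else out


def com_height(theta, beta, profile: AnthropometricProfile):
    """Exact two-link COM height ``l1*cos(theta) + (l2-r)*cos(theta-beta) + r`` (m)."""
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    h = (
        profile.l1 * np.cos(theta)
        + (profile.l2 - profile.r) * np.cos(theta - beta)
        + profile.r
    )
    return float(h) if h.ndim == 0 else h


def vertical_excursion_geometric(theta, beta, profile: AnthropometricProfile):
    """COM droop ``L - h(theta, beta)`` (m); zero when upright.

    Evaluated as ``l1*(1 - cos(theta)) + (l2 - r)*(1 - cos(theta - beta))``
    so the upright case is exactly zero in floating point.
    """
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    dh = profile.l1 * (1.0 - np.cos(theta)) + (profile.l2 - profile.r) * (
        1.0 - np.cos(theta - beta)
    )
    return float(dh) if dh.ndim == 0 else dh


def _rk4_step(theta, theta_dot, dt, omega_sq):
    # theta'' = omega_sq * theta, integrated as a first-order pair
    def f(y):
        return np.array([y[1], omega_sq * y[0]])

    y = np.array([theta, theta_dot])
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_single_support(
    state0: PendulumState,
    rho: float,
    profile: AnthropometricProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    duration: float = 0.5,
    dt: float = 1e-3,
    beta: float | None = None,
) -> COMTrajectory:
    """Integrate the linearized single-support dynamics with fixed-step RK4.

    The knee angle is held constant at ``beta`` (default: the initial
    state's ``beta_r``) — the model treats it as small during single
    support.  COM height is evaluated from the exact two-link geometry at
    every sample.
    """
    if dt <= 0 or duration < dt:
        raise IntegrationError("require dt > 0 and duration >= dt")
    if rho >= 2.0:
        raise DomainError("single-support dynamics require rho < 2")
    if beta is None:
        beta = state0.beta_r
    omega_sq = (constants.g / profile.L) * (2.0 - rho)
    n = int(round(duration / dt))
    t = state0.t + dt * np.arange(n + 1)
    theta = np.empty(n + 1)
    theta_dot = np.empty(n + 1)
    theta[0], theta_dot[0] = state0.theta_r, state0.theta_dot
    y = np.array([state0.theta_r, state0.theta_dot])
    for i in range(n):
        y = _rk4_step(y[0], y[1], dt, omega_sq)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={t[i + 1]:.6f} s")
        theta[i + 1], theta_dot[i + 1] = y
    h = com_height(theta, beta, profile)
    return COMTrajectory(t=t, theta=theta, theta_dot=theta_dot, h=h, L=profile.L)


def moment_balance_residual(
    traj: COMTrajectory,
    profile: AnthropometricProfile,
    rho: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    beta: float = 0.0,
    Liv: float | None = None,
) -> np.ndarray:
    """Diagnostic residual of the moment balance about the contact point,
    ``m*(g + ydd)*(x - xa) - m*xdd*(y - ya)``, evaluated along a simulated
    trajectory with finite-difference accelerations (N*m units).

    The linearized equation of motion keeps only the leading terms of
    this balance, so the residual is not numerically zero; it scales
    linearly with the trajectory amplitude and serves as a qualitative
    consistency probe, not an error bound.
    """
    if Liv is None:
        Liv = contact_distance(profile)
    L, l2, r, m = profile.L, profile.l2, profile.r, profile.m
    theta_p = (L * rho / Liv) * traj.theta + ((l2 - r) / Liv) * beta
    x = -(Liv * theta_p - r * (traj.theta - beta))
    y = np.full_like(x, Liv)
    dt = traj.t[1] - traj.t[0]
    xdd = np.gradient(np.gradient(x, dt), dt)
    ydd = np.gradient(np.gradient(y, dt), dt)
    return m * (constants.g + ydd) * x - m * xdd * y
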