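"""Gait-event detection and per-step spatiotemporal parameters.

Heel strike is operationalized as the instant the heel marker reaches a
local minimum of its vertical coordinate; consecutive same-side strikes
bound one gait cycle.  The stride is the sagittal (forward) distance
between the two heel landings of a cycle, the step length is half the
stride, and the per-step roll factor follows from ``rho = 1 + f/(Sl - f)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline

from .errors import ArcGaitError, ConfigError, DomainError, SingularStepError
from .model import roll_factor_from_step

__all__ = [
    "MarkerTrajectory",
    "GaitEvents",
    "StepRecord",
    "smooth_trajectory",
    "detect_heel_strikes",
    "compute_steps",
    "cadence_from_events",
]

log = logging.getLogger(__name__)

DEFAULT_AXES = {"forward": 0, "lateral": 1, "vertical": 2}


@dataclass(frozen=True)
class MarkerTrajectory:
    """Uniformly sampled 3-D marker track.

    ``t`` are sample times (s), ``pos`` an (n, 3) position array (m) whose
    columns are named by the ``axes`` mapping (forward/lateral/vertical),
    ``label`` the marker name (e.g. ``left-heel``).
    """

    t: np.ndarray
    pos: np.ndarray
    label: str = "marker"
    axes: dict = field(default_factory=lambda: dict(DEFAULT_AXES))

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        pos = np.asarray(self.pos, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] != t.shape[0]:
            raise ConfigError("pos must be (n, 3) matching t")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pos", pos)
        if t.size >= 2:
            dts = np.diff(t)
            if np.any(dts <= 0) or np.ptp(dts) > 1e-9:
                raise ConfigError("marker sampling must be uniform and increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(pos)):
            raise ConfigError("marker trajectory contains non-finite samples")
        missing = {"forward", "vertical"} - set(self.axes)
        if missing:
            raise ConfigError(f"axis mapping missing {sorted(missing)}")

    @property
    def rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def vertical(self) -> np.ndarray:
        return self.pos[:, self.axes["vertical"]]

    @property
    def forward(self) -> np.ndarray:
        return self.pos[:, self.axes["forward"]]


@dataclass(frozen=True)
class GaitEvents:
    """Heel-strike times (s) of one side and the gait cycles (pairs of
    consecutive strikes) that pass the duration plausibility gate."""

    heel_strikes: np.ndarray
    cycles: list
    side: str = "left"

    def __post_init__(self) -> None:
        hs = np.asarray(self.heel_strikes, dtype=float)
        object.__setattr__(self, "heel_strikes", hs)
        if hs.size >= 2 and np.any(np.diff(hs) <= 0):
            raise DomainError("heel-strike times must strictly increase")


@dataclass
class StepRecord:
    """One gait step: stride and step length (m), step duration (s), the
    roll factor from the step, the side, an optional true style label and
    the singularity flag for steps with ``Sl == f``."""

    stride_length: float
    step_length: float
    duration: float
    rho: float
    side: str = "left"
    label: str | None = None
    singular: bool = False
    t_strike: float = float("nan")

    def __post_init__(self) -> None:
        if abs(self.step_length - self.stride_length / 2.0) > 1e-9:
            raise DomainError("step_length must equal stride_length/2")
        if not self.duration > 0:
            raise DomainError("step duration must be strictly positive")


def smooth_trajectory(
    traj: MarkerTrajectory,
    method: str = "lowpass",
    cutoff_hz: float = 6.0,
    spline_lam: float | None = None,
) -> MarkerTrajectory:
    """Smooth a marker trajectory on its own sampling grid.

    ``method='lowpass'`` (default) applies a zero-phase 4th-order
    Butterworth filter at ``cutoff_hz`` (6 Hz is the customary kinematic
    cutoff at gait frequencies); ``method='spline'`` fits a smoothing
    spline per coordinate (``spline_lam`` is its penalty, GCV-chosen when
    None).  Both preserve a constant signal and introduce no phase lag.
    """
    n = traj.t.size
    if n < 16:
        raise ArcGaitError("trajectory too short to smooth (< 16 samples)")
    if method == "lowpass":
        nyq = 0.5 * traj.rate
        if not 0 < cutoff_hz < nyq:
            raise ConfigError(f"cutoff {cutoff_hz} Hz outside (0, {nyq}) Hz")
        sos = signal.butter(4, cutoff_hz / nyq, output="sos")
        smoothed = signal.sosfiltfilt(sos, traj.pos, axis=0)
    elif method == "spline":
        smoothed = np.column_stack(
            [
                make_smoothing_spline(traj.t, traj.pos[:, j], lam=spline_lam)(traj.t)
                for j in range(3)
            ]
        )
    else:
        raise ConfigError(f"unknown smoothing method {method!r}")
    return replace(traj, pos=smoothed)


def detect_heel_strikes(
    heel: MarkerTrajectory,
    min_separation_s: float = 0.4,
    prominence_m: float = 0.003,
    cycle_bounds_s: tuple[float, float] = (0.4, 3.0),
    side: str = "left",
) -> GaitEvents:
    """Detect heel strikes as local minima of the vertical heel coordinate.

    Minima are gated by a minimum inter-event separation and a prominence
    threshold so that noise wiggles and quiet standing do not register.
    Cycles are consecutive strike pairs whose duration falls inside the
    plausibility bounds.  When no minimum qualifies, an empty event set is
    returned with a warning rather than an exception.
    """
    if heel.t.size < 2 or heel.t[-1] - heel.t[0] < 2.0:
        raise ArcGaitError("need >= 2 s of marker data for event detection")
    z = heel.vertical
    distance = max(1, int(round(min_separation_s * heel.rate)))
    idx, _ = signal.find_peaks(-z, distance=distance, prominence=prominence_m)
    if idx.size == 0:
        warnings.warn("no heel strikes detected", stacklevel=2)
        return GaitEvents(heel_strikes=np.array([]), cycles=[], side=side)
    times = heel.t[idx]
    lo, hi = cycle_bounds_s
    cycles = [
        (t0, t1) for t0, t1 in zip(times[:-1], times[1:]) if lo <= t1 - t0 <= hi
    ]
    log.info(
        "detect_heel_strikes: %d strikes, %d plausible cycles", times.size, len(cycles)
    )
    return GaitEvents(heel_strikes=times, cycles=cycles, side=side)


def compute_steps(
    events: GaitEvents,
    heel: MarkerTrajectory,
    f: float,
    mode: str = "overground",
    belt_speed: float | None = None,
) -> list[StepRecord]:
    """Per-step spatiotemporal parameters from detected cycles.

    Overground, the stride is the absolute forward displacement of the
    heel between the two strikes of a cycle; on a treadmill the forward
    coordinate is quasi-stationary, so the stride falls back to
    ``belt_speed * cycle_time``.  Each cycle yields one record with
    ``Sl = stride/2``, ``duration = cycle_time/2`` and the roll factor
    from ``Sl`` (singular steps, ``Sl == f``, are flagged instead of
    raising — the classifier maps them to the small-broken-step style).
    """
    if mode not in ("overground", "treadmill"):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode == "treadmill" and (belt_speed is None or belt_speed <= 0):
        raise ConfigError("treadmill mode requires a positive belt_speed")
    if "forward" not in heel.axes:
        raise ConfigError("marker trajectory lacks a forward axis")
    records: list[StepRecord] = []
    xf = heel.forward
    for t0, t1 in events.cycles:
        cycle = t1 - t0
        if mode == "overground":
            x0 = np.interp(t0, heel.t, xf)
            x1 = np.interp(t1, heel.t, xf)
            stride = abs(x1 - x0)
        else:
            stride = belt_speed * cycle
        sl = stride / 2.0
        try:
            rho = roll_factor_from_step(sl, f)
            singular = False
        except SingularStepError:
            rho, singular = float("nan"), True
        records.append(
            StepRecord(
                stride_length=stride,
                step_length=sl,
                duration=cycle / 2.0,
                rho=rho,
                side=events.side,
                singular=singular,
                t_strike=t0,
            )
        )
    log.info("compute_steps: %d records from %d cycles", len(records), len(events.cycles))
    return records


def cadence_from_events(
    events: GaitEvents, window_s: float, steps_per_event: int = 1
) -> float:
    """Cadence (steps/min) by counting steps over a test window.

    ``steps_per_event`` converts detected events to steps: 1 when every
    strike of both feet is an event, 2 when only one side's heel was
    tracked (each of its cycles spans two steps).
    """
    if window_s <= 0:
        raise DomainError("window must be strictly positive")
    n = events.heel_strikes.size
    if n == 0:
        warnings.warn("no events: cadence reported as 0", stacklevel=2)
        return 0.0
    return steps_per_event * n / window_s * 60.0
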