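"""Joint-angle landmarks of the gait cycle.

A gait cycle (heel strike to the next same-side heel strike) is divided
into the seven classical phases — loading response (LR), mid-stance
(MSt), terminal stance (TSt), pre-swing (PSw), initial swing (ISw),
mid-swing (MSw), terminal swing (TSw) — and eight landmark angles are
read off the sagittal hip/knee/ankle curves:

* ``Hmax`` / ``Hmin`` — peak thigh flexion / extension (their difference
  is the thigh span, closely tied to step length);
* ``Kmax1`` — stance (loading-response) knee flexion peak, the shock
  absorber; ``Kmax2`` — swing knee flexion peak, the foot-clearance peak;
* ``Amax1`` — dorsiflexion at heel strike (heel-rocker), ``Amin1`` —
  plantarflexion at foot-flat (ankle-rocker), ``Amax2`` — dorsiflexion at
  heel-off (forefoot-rocker), ``Amin2`` — plantarflexion at toe-off
  (toe-rocker).

Sign conventions: flexion positive for hip and knee, dorsiflexion
positive for the ankle, all in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArcGaitError, ConfigError, DomainError
from .events import GaitEvents, StepRecord

__all__ = [
    "PhaseWindows",
    "JointAngleSeries",
    "CycleSeries",
    "FeaturePoints",
    "LANDMARKS",
    "segment_cycles",
    "extract_feature_points",
    "feature_vs_rho_table",
]

LANDMARKS = ("Hmax", "Hmin", "Kmax1", "Kmax2", "Amax1", "Amin1", "Amax2", "Amin2")

_ANGLE_RANGE = (-90.0, 120.0)


@dataclass(frozen=True)
class PhaseWindows:
    """Phase boundaries in % of gait cycle (contiguous cover of [0, 100]).

    Defaults follow the customary division: LR 0-10, MSt 10-30, TSt
    30-50, PSw 50-60, ISw 60-73, MSw 73-87, TSw 87-100.
    """

    LR: tuple = (0.0, 10.0)
    MSt: tuple = (10.0, 30.0)
    TSt: tuple = (30.0, 50.0)
    PSw: tuple = (50.0, 60.0)
    ISw: tuple = (60.0, 73.0)
    MSw: tuple = (73.0, 87.0)
    TSw: tuple = (87.0, 100.0)
    #: width of the initial-contact window used for Amax1 (% cycle)
    initial_contact: float = 3.0

    def __post_init__(self) -> None:
        names = ("LR", "MSt", "TSt", "PSw", "ISw", "MSw", "TSw")
        spans = [getattr(self, n) for n in names]
        if spans[0][0] != 0.0 or spans[-1][1] != 100.0:
            raise ConfigError("phase windows must cover [0, 100]% cycle")
        for (a, b), (c, _) in zip(spans[:-1], spans[1:]):
            if b != c or a >= b:
                raise ConfigError("phase windows must be contiguous and increasing")


DEFAULT_WINDOWS = PhaseWindows()


@dataclass(frozen=True)
class JointAngleSeries:
    """Time-stamped sagittal hip/knee/ankle angles (deg) of one side."""

    t: np.ndarray
    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    side: str = "left"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        for name in ("hip", "knee", "ankle"):
            a = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, a)
            if a.shape != t.shape:
                raise ConfigError(f"{name} series must share the time grid")
            if np.any(a < _ANGLE_RANGE[0]) or np.any(a > _ANGLE_RANGE[1]):
                raise DomainError(
                    f"{name} angles outside plausibility range {_ANGLE_RANGE} deg"
                )


@dataclass(frozen=True)
class CycleSeries:
    """One gait cycle resampled to a fixed %-cycle grid."""

    pct: np.ndarray
    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    t_start: float
    t_end: float


@dataclass(frozen=True)
class FeaturePoints:
    """The eight landmark angles of one cycle (deg), the %-cycle location
    of each, the derived hip span ``Hmax - Hmin`` and a degeneracy flag
    for flat input curves."""

    values: dict
    locations: dict
    degenerate: bool = False

    def __post_init__(self) -> None:
        missing = set(LANDMARKS) - set(self.values)
        if missing:
            raise ArcGaitError(f"missing landmarks {sorted(missing)}")
        if not self.degenerate and self.values["Hmax"] < self.values["Hmin"]:
            raise DomainError("Hmax < Hmin")

    @property
    def hip_span(self) -> float:
        return self.values["Hmax"] - self.values["Hmin"]

    def __getattr__(self, name):
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)


def segment_cycles(
    series: JointAngleSeries, events: GaitEvents, n_points: int = 101
) -> list[CycleSeries]:
    """Cut the angle series at consecutive same-side heel strikes and
    resample each cycle to ``n_points`` samples on a 0-100 %-cycle grid.
    Returns an empty list when no complete cycle is available."""
    strikes = events.heel_strikes
    if strikes.size < 2:
        return []
    pct = np.linspace(0.0, 100.0, n_points)
    out = []
    for t0, t1 in zip(strikes[:-1], strikes[1:]):
        if t0 < series.t[0] - 1e-9 or t1 > series.t[-1] + 1e-9:
            continue
        ts = t0 + (t1 - t0) * pct / 100.0
        out.append(
            CycleSeries(
                pct=pct,
                hip=np.interp(ts, series.t, series.hip),
                knee=np.interp(ts, series.t, series.knee),
                ankle=np.interp(ts, series.t, series.ankle),
                t_start=t0,
                t_end=t1,
            )
        )
    return out


def _windowed_extremum(pct, y, lo, hi, kind):
    mask = (pct >= lo) & (pct <= hi)
    idx = np.nonzero(mask)[0]
    vals = y[idx]
    j = idx[int(np.argmax(vals) if kind == "max" else np.argmin(vals))]
    # argmax/argmin take the first occurrence: ties break to earliest % cycle
    return float(y[j]), float(pct[j])


def _stance_knee_peak(pct, knee, stance_end):
    """Loading-response knee peak: the largest *interior* local maximum
    inside the stance window, so the flexion ramp rising toward the
    swing peak at the window's edge is not mistaken for it.  Falls back
    to the windowed maximum when stance holds no interior peak."""
    from scipy.signal import argrelmax

    mask = (pct >= 0) & (pct <= stance_end)
    idx = np.nonzero(mask)[0]
    seg = knee[idx]
    peaks = argrelmax(seg)[0]
    if peaks.size == 0:
        return _windowed_extremum(pct, knee, 0, stance_end, "max")
    j = idx[peaks[int(np.argmax(seg[peaks]))]]
    return float(knee[j]), float(pct[j])


def extract_feature_points(
    cycle: CycleSeries, windows: PhaseWindows = DEFAULT_WINDOWS, flat_tol: float = 1e-9
) -> FeaturePoints:
    """Read the eight landmarks off one normalized cycle.

    Hip extremes are global; the knee peaks are split into the stance
    window (``Kmax1``, up to the start of pre-swing) and the global
    flexion maximum (``Kmax2``); the four ankle landmarks are windowed
    extrema at initial contact, LR+MSt, TSt and PSw+ISw respectively.
    A flat (constant) joint curve marks the result degenerate.
    """
    pct = cycle.pct
    degenerate = any(
        np.ptp(y) < flat_tol for y in (cycle.hip, cycle.knee, cycle.ankle)
    )
    values, locs = {}, {}
    values["Hmax"], locs["Hmax"] = _windowed_extremum(pct, cycle.hip, 0, 100, "max")
    values["Hmin"], locs["Hmin"] = _windowed_extremum(pct, cycle.hip, 0, 100, "min")
    stance_end = windows.PSw[0]
    values["Kmax1"], locs["Kmax1"] = _stance_knee_peak(pct, cycle.knee, stance_end)
    values["Kmax2"], locs["Kmax2"] = _windowed_extremum(pct, cycle.knee, 0, 100, "max")
    values["Amax1"], locs["Amax1"] = _windowed_extremum(
        pct, cycle.ankle, 0, windows.initial_contact, "max"
    )
    values["Amin1"], locs["Amin1"] = _windowed_extremum(
        pct, cycle.ankle, windows.LR[0], windows.MSt[1], "min"
    )
    values["Amax2"], locs["Amax2"] = _windowed_extremum(
        pct, cycle.ankle, windows.TSt[0], windows.TSt[1], "max"
    )
    values["Amin2"], locs["Amin2"] = _windowed_extremum(
        pct, cycle.ankle, windows.PSw[0], windows.ISw[1], "min"
    )
    return FeaturePoints(values=values, locations=locs, degenerate=degenerate)


def feature_vs_rho_table(
    records: list[StepRecord], features: list[FeaturePoints]
) -> pd.DataFrame:
    """Pair per-cycle roll factors with landmark values in a tidy table
    (one row per cycle, columns rho + the eight landmarks + hip_span),
    dropping degenerate cycles.  Inputs must be time-aligned and of equal
    length."""
    if len(records) != len(features):
        raise ArcGaitError(
            f"records ({len(records)}) and features ({len(features)}) differ in length"
        )
    rows = []
    for rec, fp in zip(records, features):
        if fp.degenerate:
            continue
        row = {"rho": rec.rho, **fp.values, "hip_span": fp.hip_span}
        rows.append(row)
    return pd.DataFrame(rows, columns=["rho", *LANDMARKS, "hip_span"])
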