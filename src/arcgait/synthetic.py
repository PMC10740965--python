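"""Labelled synthetic gait data with ground-truth manifests.

The generator emulates the measurement protocols the model was validated
on — 100 steps per walking pattern, 100 Hz motion capture — with full
knowledge of the planted truth:

* **step sequences**: the roll factor is drawn from a style-conditional
  distribution (normal walking U(1.4, 1.8), the observed range of normal
  treadmill walking; inefficient U(2.1, 3.5); small broken steps draw
  the step length below the foot length instead), step length follows
  ``Sl = rho*f/(rho - 1)`` and the step duration is the reciprocal of the
  model cadence in the pendular band (a slow-cadence draw otherwise);
* **heel-marker trajectories**: consecutive steps are paired into
  left-foot gait cycles; the vertical coordinate is a raised-cosine arc
  per cycle whose minimum falls exactly on each planted heel-strike time,
  and the forward coordinate advances one stride per cycle along a smooth
  profile with zero velocity at the strikes (overground) or is pulled
  back by the belt displacement (treadmill);
* **joint-angle curves**: each landmark is placed at its canonical
  %-cycle location with a value linear in the cycle's roll factor, and a
  shape-preserving (monotone cubic) interpolant threads the landmarks so
  windowed extrema recover the planted values exactly.

All randomness flows through one seeded generator; identical spec + seed
reproduce identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ArcGaitError, ConfigError, DomainError
from .events import DEFAULT_AXES, MarkerTrajectory, StepRecord
from .features import LANDMARKS, JointAngleSeries
from .model import cadence_per_second, roll_factor_from_step, step_length_from_rho
from .profiles import DEFAULT_CONSTANTS, DEFAULT_PROFILE, AnthropometricProfile, ModelConstants
from .recognition import WalkStyle

__all__ = [
    "SyntheticGaitSpec",
    "SyntheticBundle",
    "DEFAULT_LINEAR_MAPS",
    "generate_step_sequence",
    "generate_heel_trajectory",
    "generate_joint_angles",
    "generate_bundle",
]

#: style-conditional defaults: the roll-factor (or, for broken steps,
#: step-length) distribution each walking style is drawn from.
DEFAULT_STYLE_DISTS = {
    WalkStyle.INVERTED_PENDULUM: ("uniform", 1.4, 1.8),
    WalkStyle.INEFFICIENT: ("uniform", 2.1, 3.5),
    WalkStyle.SMALL_BROKEN_STEP: ("uniform_sl_frac", 0.3, 0.9),  # fractions of f
}

#: landmark = slope*rho + intercept (deg), qualitative trends of normal
#: walking: hip/knee landmarks shrink as rho grows (shorter steps), the
#: ankle rocker angles flatten toward zero.
DEFAULT_LINEAR_MAPS = {
    "Hmax": (-25.0, 70.0),
    "Hmin": (20.0, -50.0),
    "Kmax1": (-20.0, 48.0),
    "Kmax2": (-30.0, 110.0),
    "Amax1": (10.0, -12.0),
    "Amin1": (8.0, -18.0),
    "Amax2": (8.0, -4.0),
    "Amin2": (25.0, -55.0),
}

#: canonical %-cycle locations where each landmark is planted
LANDMARK_PCT = {
    "Hmax": 88.0,
    "Hmin": 50.0,
    "Kmax1": 15.0,
    "Kmax2": 70.0,
    "Amax1": 0.0,
    "Amin1": 7.0,
    "Amax2": 45.0,
    "Amin2": 62.0,
}

_KNEE_BASELINE = 3.0  # deg, knee angle between the two flexion peaks


@dataclass(frozen=True)
class SyntheticGaitSpec:
    """Recipe for one synthetic walking bout.

    ``style`` picks the band-respecting distribution (overridable via
    ``rho_dist``); noise levels are the marker noise SD (m), angle noise
    SD (deg) and per-step length/duration noise SDs (m, s).  ``seed`` is
    mandatory: every stochastic call derives from it.
    """

    style: WalkStyle = WalkStyle.INVERTED_PENDULUM
    n_steps: int = 100
    rho_dist: tuple | None = None
    profile: AnthropometricProfile = DEFAULT_PROFILE
    constants: ModelConstants = DEFAULT_CONSTANTS
    noise_sd_marker: float = 0.0
    noise_sd_angle: float = 0.0
    noise_sd_step: float = 0.0
    noise_sd_duration: float = 0.0
    sample_rate: float = 100.0
    mode: str = "overground"
    seed: int = 0
    #: slow-cadence step-duration distribution outside the pendular band
    #: (s; keeps cycle durations inside the detector's plausibility gate)
    slow_duration_range: tuple = (0.9, 1.4)

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        for nm in ("noise_sd_marker", "noise_sd_angle", "noise_sd_step", "noise_sd_duration"):
            if getattr(self, nm) < 0:
                raise ConfigError(f"{nm} must be non-negative")
        if self.mode not in ("overground", "treadmill"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.seed is None:
            raise ConfigError("a seed is mandatory for synthetic generation")

    @property
    def dist(self) -> tuple:
        return self.rho_dist if self.rho_dist is not None else DEFAULT_STYLE_DISTS[self.style]


@dataclass(frozen=True)
class SyntheticBundle:
    """Everything one bout produces: labelled step records, the heel
    marker trajectory, joint angles, and the ground-truth manifest of all
    planted quantities."""

    steps: list
    heel: MarkerTrajectory
    angles: JointAngleSeries
    manifest: dict


def _draw(dist: tuple, n: int, rng: np.random.Generator, f: float) -> tuple:
    """Draw n values; returns (rho_array_or_None, sl_array)."""
    kind = dist[0]
    if kind == "uniform":
        rho = rng.uniform(dist[1], dist[2], n)
        return rho, step_length_from_rho(rho, f)
    if kind == "constant":
        rho = np.full(n, float(dist[1]))
        return rho, step_length_from_rho(rho, f)
    if kind == "uniform_sl_frac":
        sl = rng.uniform(dist[1] * f, dist[2] * f, n)
        return None, sl
    if kind == "constant_sl":
        return None, np.full(n, float(dist[1]))
    raise ConfigError(f"unknown distribution {kind!r}")


def _band_warnings(rho: np.ndarray | None, sl: np.ndarray, f: float) -> list:
    warns = []
    if rho is not None and (np.any(rho <= 1.0) | np.any(rho >= 2.0)) and (
        np.any((rho > 1.0) & (rho < 2.0))
    ):
        warns.append("rho distribution straddles a band boundary")
    below, above = np.any(sl < f), np.any(sl > f)
    if below and above:
        warns.append("step-length draws straddle the Sl = f singularity")
    return warns


def generate_step_sequence(spec: SyntheticGaitSpec):
    """Draw a labelled step sequence; returns ``(records, manifest)``.

    The manifest stores the planted roll factors, noise-free step lengths
    and durations, the realized (noisy) values and any band-straddling
    warnings; it is reproducible exactly from the spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    f = spec.profile.f
    rho_planted, sl_clean = _draw(spec.dist, spec.n_steps, rng, f)
    pendular = rho_planted is not None and np.all((rho_planted > 1) & (rho_planted < 2))
    if pendular:
        dur_clean = 1.0 / cadence_per_second(
            rho_planted, spec.profile.L, spec.constants.xi, spec.constants.g
        )
    else:
        dur_clean = rng.uniform(*spec.slow_duration_range, spec.n_steps)
    sl = sl_clean + rng.normal(0.0, spec.noise_sd_step, spec.n_steps)
    sl = np.maximum(sl, 1e-3)
    dur = np.maximum(
        dur_clean + rng.normal(0.0, spec.noise_sd_duration, spec.n_steps), 0.05
    )
    records = []
    t = 0.0
    for k in range(spec.n_steps):
        try:
            rho_k = roll_factor_from_step(float(sl[k]), f)
            singular = False
        except ArcGaitError:
            rho_k, singular = float("nan"), True
        records.append(
            StepRecord(
                stride_length=2.0 * float(sl[k]),
                step_length=float(sl[k]),
                duration=float(dur[k]),
                rho=rho_k,
                label=spec.style.value,
                singular=singular,
                t_strike=t,
            )
        )
        t += float(dur[k])
    manifest = {
        "style": spec.style.value,
        "seed": spec.seed,
        "rho_planted": None if rho_planted is None else rho_planted.tolist(),
        "step_length_clean_m": sl_clean.tolist(),
        "duration_clean_s": dur_clean.tolist(),
        "step_length_m": sl.tolist(),
        "duration_s": dur.tolist(),
        "warnings": _band_warnings(rho_planted, sl, f),
    }
    for w in manifest["warnings"]:
        warnings.warn(w, stacklevel=2)
    return records, manifest


def _cycles_from_steps(steps: list, fs: float) -> tuple:
    """Pair consecutive steps into left-foot gait cycles.

    Cycle durations are snapped to whole samples of the ``fs`` grid so
    that every planted heel strike falls exactly on a sample.
    """
    n_pairs = len(steps) // 2
    if n_pairs < 1:
        raise ArcGaitError("need at least 2 steps to form a gait cycle")
    strides = np.array(
        [steps[2 * j].step_length + steps[2 * j + 1].step_length for j in range(n_pairs)]
    )
    cycles = np.array(
        [steps[2 * j].duration + steps[2 * j + 1].duration for j in range(n_pairs)]
    )
    cycles = np.round(cycles * fs) / fs
    dropped = len(steps) - 2 * n_pairs
    return strides, cycles, dropped


def generate_heel_trajectory(
    steps: list,
    spec: SyntheticGaitSpec,
    arc_height: float = 0.06,
    ground_clearance: float = 0.02,
):
    """Left-heel marker trajectory with planted heel-strike times.

    Returns ``(trajectory, manifest)``.  The vertical coordinate of cycle
    j is ``z0 + (A/2)*(1 - cos(2*pi*u))`` with ``u`` the cycle fraction,
    so its minima fall exactly on the strike times; the forward
    coordinate follows the cycloid-like profile ``u - sin(2*pi*u)/(2*pi)``
    scaled by the stride (heel velocity is zero at the strikes, as it is
    at real heel contact).  Treadmill mode subtracts the belt displacement
    (one stride per cycle), keeping the marker bounded.
    """
    fs = spec.sample_rate
    strides, cycles, dropped = _cycles_from_steps(steps, fs)
    if fs < 10.0 / cycles.min():
        raise ConfigError(
            f"sample rate {fs} Hz too low for cycles of {cycles.min():.3f} s"
        )
    strike_t = np.concatenate([[0.0], np.cumsum(cycles)])
    pad = np.round(0.4 * float(cycles[0]) * fs) / fs
    strike_t = strike_t + pad
    t_end = strike_t[-1] + 0.4 * float(cycles[-1])
    n = int(np.floor(t_end * fs)) + 1
    t = np.arange(n) / fs
    # index of the cycle governing each sample (edge samples reuse the
    # first/last cycle's arc, which rises away from the strike)
    j = np.clip(np.searchsorted(strike_t, t, side="right") - 1, 0, len(cycles) - 1)
    u = (t - strike_t[j]) / cycles[j]
    z = ground_clearance + 0.5 * arc_height * (1.0 - np.cos(2.0 * np.pi * u))
    x_base = np.concatenate([[0.0], np.cumsum(strides)])
    prof = u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)
    if spec.mode == "overground":
        x = x_base[j] + strides[j] * prof
    else:
        x = -strides[j] * np.sin(2.0 * np.pi * u) / (2.0 * np.pi)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if spec.noise_sd_marker > 0:
        z = z + rng.normal(0.0, spec.noise_sd_marker, n)
        x = x + rng.normal(0.0, spec.noise_sd_marker, n)
    pos = np.column_stack([x, np.zeros(n), z])
    traj = MarkerTrajectory(t=t, pos=pos, label="left-heel", axes=dict(DEFAULT_AXES))
    rho_cycle = []
    f = spec.profile.f
    for s in strides:
        try:
            rho_cycle.append(float(roll_factor_from_step(s / 2.0, f)))
        except ArcGaitError:
            rho_cycle.append(float("nan"))
    manifest = {
        "strike_times_s": strike_t.tolist(),
        "cycle_durations_s": cycles.tolist(),
        "strides_m": strides.tolist(),
        "rho_per_cycle": rho_cycle,
        "mode": spec.mode,
        "belt_speed_m_per_s": float(strides.sum() / cycles.sum())
        if spec.mode == "treadmill"
        else None,
        "steps_dropped_odd": dropped,
        "sample_rate_hz": fs,
    }
    return traj, manifest


def _cycle_curves(pct: np.ndarray, lm: dict) -> tuple:
    """Evaluate hip/knee/ankle template curves through planted landmarks."""
    # hip flexion peaks in terminal swing; the cycle-boundary value sits
    # between the extremes so adjacent cycles join continuously without
    # masking each other's planted peaks
    hip_boundary = lm["Hmin"] + 0.3 * (lm["Hmax"] - lm["Hmin"])
    hip = PchipInterpolator(
        [0.0, 50.0, 88.0, 100.0],
        [hip_boundary, lm["Hmin"], lm["Hmax"], hip_boundary],
    )(pct)
    knee = PchipInterpolator(
        [0.0, 15.0, 40.0, 70.0, 100.0],
        [_KNEE_BASELINE, lm["Kmax1"], _KNEE_BASELINE * 0.5, lm["Kmax2"], _KNEE_BASELINE],
    )(pct)
    ankle = PchipInterpolator(
        [0.0, 7.0, 45.0, 62.0, 80.0, 100.0],
        [lm["Amax1"], lm["Amin1"], lm["Amax2"], lm["Amin2"], 0.0, lm["Amax1"]],
    )(pct)
    return hip, knee, ankle


def _check_ordering(lm: dict) -> None:
    if lm["Hmax"] <= lm["Hmin"]:
        raise DomainError("landmark maps give Hmax <= Hmin")
    if lm["Kmax2"] <= lm["Kmax1"]:
        raise DomainError("landmark maps give Kmax2 <= Kmax1 (swing peak must dominate)")
    if lm["Kmax1"] <= _KNEE_BASELINE:
        raise DomainError("stance knee peak must exceed the knee baseline")
    if lm["Amax1"] <= lm["Amin1"] or lm["Amax2"] <= lm["Amin2"]:
        raise DomainError("ankle landmark ordering violated (max <= min)")
    if lm["Amin2"] >= 0.0 or lm["Amax2"] <= 0.0:
        raise DomainError("ankle template requires Amin2 < 0 < Amax2")


def generate_joint_angles(
    steps: list,
    spec: SyntheticGaitSpec,
    linear_maps: dict = None,
    strike_times: np.ndarray | None = None,
):
    """Hip/knee/ankle series whose landmarks vary linearly with rho.

    Per cycle, each landmark value is ``slope*rho + intercept`` plus
    Gaussian noise (``noise_sd_angle``); the curves thread the landmarks
    at their canonical %-cycle locations with a monotone cubic, so the
    windowed landmark extraction recovers the planted values exactly in
    the noise-free case.  Returns ``(JointAngleSeries, manifest)`` where
    the manifest lists every planted landmark per cycle.
    """
    if linear_maps is None:
        linear_maps = DEFAULT_LINEAR_MAPS
    missing = set(LANDMARKS) - set(linear_maps)
    if missing:
        raise ConfigError(f"linear_maps missing {sorted(missing)}")
    fs = spec.sample_rate
    strides, cycles, _ = _cycles_from_steps(steps, fs)
    f = spec.profile.f
    if strike_times is None:
        pad = np.round(0.4 * float(cycles[0]) * fs) / fs
        strike_times = pad + np.concatenate([[0.0], np.cumsum(cycles)])
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    t0, t1 = float(strike_times[0]), float(strike_times[-1])
    n = int(np.round((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    hip = np.empty(n)
    knee = np.empty(n)
    ankle = np.empty(n)
    planted = []
    for jc in range(len(cycles)):
        rho_c = roll_factor_from_step(strides[jc] / 2.0, f)
        # the landmark maps are calibrated on the normal walking band;
        # outside it, curves are generated at the nearest band edge
        rho_lm = float(np.clip(rho_c, 1.1, 1.9))
        lm = {
            k: s * rho_lm + b + (rng.normal(0.0, spec.noise_sd_angle) if spec.noise_sd_angle else 0.0)
            for k, (s, b) in linear_maps.items()
        }
        _check_ordering(lm)
        mask = (t >= strike_times[jc] - 1e-12) & (t <= strike_times[jc + 1] + 1e-12)
        pct = (t[mask] - strike_times[jc]) / cycles[jc] * 100.0
        hip[mask], knee[mask], ankle[mask] = _cycle_curves(np.clip(pct, 0, 100), lm)
        planted.append(
            {
                "rho": float(rho_c),
                "rho_landmarks": rho_lm,
                **{k: float(v) for k, v in lm.items()},
            }
        )
    series = JointAngleSeries(t=t, hip=hip, knee=knee, ankle=ankle, side="left")
    manifest = {
        "landmarks_per_cycle": planted,
        "landmark_pct": dict(LANDMARK_PCT),
        "linear_maps": {k: list(v) for k, v in linear_maps.items()},
    }
    return series, manifest


def generate_bundle(spec: SyntheticGaitSpec) -> SyntheticBundle:
    """One full synthetic bout: steps + heel marker + joint angles, with a
    merged ground-truth manifest."""
    steps, m_steps = generate_step_sequence(spec)
    heel, m_heel = generate_heel_trajectory(steps, spec)
    angles, m_ang = generate_joint_angles(
        steps, spec, strike_times=np.asarray(m_heel["strike_times_s"])
    )
    manifest = {"steps": m_steps, "heel": m_heel, "angles": m_ang}
    return SyntheticBundle(steps=steps, heel=heel, angles=angles, manifest=manifest)
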