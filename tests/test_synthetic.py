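"""Synthetic-gait generator: determinism, planted truths, pipeline closure."""

import numpy as np
import pytest

from arcgait import (
    WalkStyle,
    classify_records,
    compute_steps,
    detect_heel_strikes,
    smooth_trajectory,
)
from arcgait.errors import ConfigError, DomainError
from arcgait.synthetic import (
    DEFAULT_LINEAR_MAPS,
    SyntheticGaitSpec,
    generate_bundle,
    generate_heel_trajectory,
    generate_joint_angles,
    generate_step_sequence,
)


def test_seeded_determinism_and_divergence():
    spec = SyntheticGaitSpec(n_steps=30, seed=9, noise_sd_step=0.01, noise_sd_marker=0.002)
    a1, m1 = generate_step_sequence(spec)
    a2, m2 = generate_step_sequence(spec)
    assert m1 == m2
    assert [r.step_length for r in a1] == [r.step_length for r in a2]
    b, mb = generate_step_sequence(
        SyntheticGaitSpec(n_steps=30, seed=10, noise_sd_step=0.01)
    )
    assert m1["step_length_m"] != mb["step_length_m"]
    t1, h1 = generate_heel_trajectory(a1, spec)
    t2, _ = generate_heel_trajectory(a2, spec)
    assert np.array_equal(t1.pos, t2.pos)


def test_fixed_rho_step_sequence():
    """rho = 1.6 noise-free: Sl = 0.6667 m, duration = 0.5986 s per step."""
    spec = SyntheticGaitSpec(rho_dist=("constant", 1.6), n_steps=10, seed=1)
    records, manifest = generate_step_sequence(spec)
    for r in records:
        assert r.step_length == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert r.duration == pytest.approx(0.5986, abs=1e-4)
        assert r.rho == pytest.approx(1.6, abs=1e-9)
    assert manifest["warnings"] == []


def test_broken_step_sequence_fixed_sl():
    spec = SyntheticGaitSpec(
        style=WalkStyle.SMALL_BROKEN_STEP, rho_dist=("constant_sl", 0.2), n_steps=8, seed=2
    )
    records, _ = generate_step_sequence(spec)
    for r in records:
        assert r.rho == pytest.approx(-4.0, abs=1e-9)
        assert r.label == "small_broken_step"


def test_band_straddling_warns():
    spec = SyntheticGaitSpec(rho_dist=("uniform", 1.8, 2.2), n_steps=50, seed=3)
    with pytest.warns(UserWarning):
        _, manifest = generate_step_sequence(spec)
    assert manifest["warnings"]


def test_heel_trajectory_plants_detectable_minima():
    """Noise-free closure with the detector: every planted strike is
    found exactly once, within one sample."""
    spec = SyntheticGaitSpec(n_steps=60, seed=4)
    b = generate_bundle(spec)
    heel = smooth_trajectory(b.heel)
    ev = detect_heel_strikes(heel)
    planted = np.asarray(b.manifest["heel"]["strike_times_s"])
    assert ev.heel_strikes.size == planted.size
    assert np.max(np.abs(ev.heel_strikes - planted)) <= 1.0 / spec.sample_rate + 1e-9


def test_overground_forward_span_telescopes():
    spec = SyntheticGaitSpec(n_steps=20, seed=5)
    steps, _ = generate_step_sequence(spec)
    traj, manifest = generate_heel_trajectory(steps, spec)
    strikes = np.asarray(manifest["strike_times_s"])
    x0 = np.interp(strikes[0], traj.t, traj.forward)
    x1 = np.interp(strikes[-1], traj.t, traj.forward)
    assert x1 - x0 == pytest.approx(sum(manifest["strides_m"]), abs=1e-9)


def test_treadmill_forward_stays_bounded():
    spec = SyntheticGaitSpec(n_steps=100, seed=6, mode="treadmill")
    b = generate_bundle(spec)
    assert np.max(np.abs(b.heel.forward)) < 0.5
    assert b.manifest["heel"]["belt_speed_m_per_s"] > 0


def test_nyquist_guard():
    spec = SyntheticGaitSpec(n_steps=10, seed=7, sample_rate=4.0)
    steps, _ = generate_step_sequence(spec)
    with pytest.raises(ConfigError):
        generate_heel_trajectory(steps, spec)


def test_angles_constant_when_slopes_zero():
    spec = SyntheticGaitSpec(rho_dist=("constant", 1.6), n_steps=12, seed=8)
    steps, _ = generate_step_sequence(spec)
    flat_maps = {k: (0.0, v) for k, v in
                 {"Hmax": 30.0, "Hmin": -20.0, "Kmax1": 15.0, "Kmax2": 60.0,
                  "Amax1": 5.0, "Amin1": -7.0, "Amax2": 10.0, "Amin2": -20.0}.items()}
    series, manifest = generate_joint_angles(steps, spec, linear_maps=flat_maps)
    lms = manifest["landmarks_per_cycle"]
    assert all(lm["Hmax"] == 30.0 for lm in lms)
    # identical cycles -> periodic signal (cycle snaps to 1.20 s at 100 Hz)
    n_cycle = 120
    assert np.max(np.abs(series.hip[:n_cycle] - series.hip[n_cycle : 2 * n_cycle])) < 1e-9


def test_angle_landmark_ordering_enforced():
    spec = SyntheticGaitSpec(rho_dist=("constant", 1.6), n_steps=4, seed=9)
    steps, _ = generate_step_sequence(spec)
    bad = dict(DEFAULT_LINEAR_MAPS)
    bad["Hmin"] = (0.0, 80.0)  # forces Hmin > Hmax
    with pytest.raises(DomainError):
        generate_joint_angles(steps, spec, linear_maps=bad)


def test_planted_linear_map_recovered_exactly():
    """Hmax = -20 rho + 60 with zero noise: OLS recovers the line with
    R^2 = 1 from extracted landmarks."""
    from arcgait import GaitEvents, linear_fit, segment_cycles, extract_feature_points

    maps = dict(DEFAULT_LINEAR_MAPS)
    maps["Hmax"] = (-20.0, 60.0)
    spec = SyntheticGaitSpec(n_steps=80, seed=11)
    steps, _ = generate_step_sequence(spec)
    series, manifest = generate_joint_angles(steps, spec, linear_maps=maps)
    heel_tr, m_heel = generate_heel_trajectory(steps, spec)
    ev = GaitEvents(heel_strikes=np.asarray(m_heel["strike_times_s"]), cycles=[])
    cycles = segment_cycles(series, ev)
    rho = np.array([lm["rho"] for lm in manifest["landmarks_per_cycle"]])
    # planted landmark values recover the line exactly ...
    planted_hmax = np.array([lm["Hmax"] for lm in manifest["landmarks_per_cycle"]])
    fit_exact = linear_fit(rho, planted_hmax)
    assert fit_exact.slope == pytest.approx(-20.0, abs=1e-9)
    assert fit_exact.intercept == pytest.approx(60.0, abs=1e-9)
    assert fit_exact.r2 == pytest.approx(1.0, abs=1e-12)
    # ... and extraction through the %-cycle grid stays close
    hmax = np.array([extract_feature_points(c).Hmax for c in cycles])
    fit = linear_fit(rho, hmax)
    assert fit.slope == pytest.approx(-20.0, abs=0.2)
    assert fit.intercept == pytest.approx(60.0, abs=0.35)
    assert fit.r2 > 0.999


def test_full_pipeline_closure_zero_noise():
    """Master closure: generate -> detect -> steps -> rho -> classify
    reproduces the manifest labels with 100% accuracy at zero noise."""
    for style in WalkStyle:
        spec = SyntheticGaitSpec(style=style, n_steps=40, seed=13)
        b = generate_bundle(spec)
        heel = smooth_trajectory(b.heel)
        recs = compute_steps(detect_heel_strikes(heel), heel, spec.profile.f)
        assert len(recs) == len(b.manifest["heel"]["rho_per_cycle"])
        pred = classify_records(recs)
        assert all(p.value == style.value for p in pred)


def test_full_pipeline_accuracy_with_marker_noise():
    """With 2 mm marker noise, per-style accuracy stays >= 95%."""
    from arcgait import evaluate_recognition

    true, pred = [], []
    for i, style in enumerate(WalkStyle):
        spec = SyntheticGaitSpec(style=style, n_steps=100, seed=17 + i, noise_sd_marker=0.002)
        b = generate_bundle(spec)
        heel = smooth_trajectory(b.heel)
        recs = compute_steps(detect_heel_strikes(heel), heel, spec.profile.f)
        true += [style.value] * len(recs)
        pred += classify_records(recs)
    acc = evaluate_recognition(true, pred).accuracy
    assert all(a >= 95.0 for a in acc.values())
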