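"""Closed-form kinematics: hand-checked values, algebraic identities,
monotonicity and the walking-band partition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcgait import (
    AnthropometricProfile,
    DomainError,
    GeometryError,
    ModelConstants,
    SingularStepError,
    cadence,
    cadence_per_second,
    gait_speed,
    inherent_period,
    natural_frequency,
    predict_gait,
    roll_factor_from_step,
    roll_factor_gard,
    step_length_from_rho,
    swing_period,
    vertical_excursion,
)


@pytest.mark.parametrize(
    "r, L, expected",
    [(0.0, 0.9, 1.0), (0.3, 1.0, 1.0 / 0.7), (0.5, 1.0, 2.0)],
)
def test_gard_roll_factor_values(r, L, expected):
    assert roll_factor_gard(r, L) == pytest.approx(expected, rel=1e-12)


def test_gard_roll_factor_monotone_in_radius():
    rs = np.linspace(0.0, 0.8, 200)
    rho = roll_factor_gard(rs, 0.9)
    assert rho[0] == 1.0
    assert np.all(np.diff(rho) > 0)


@pytest.mark.parametrize("r, L", [(1.0, 1.0), (1.2, 1.0), (0.5, -1.0), (-0.1, 1.0)])
def test_gard_roll_factor_domain(r, L):
    with pytest.raises(DomainError):
        roll_factor_gard(r, L)


@pytest.mark.parametrize(
    "Sl, f, expected",
    [(0.50, 0.25, 2.0), (0.60, 0.25, 1.0 + 0.25 / 0.35), (0.20, 0.25, -4.0)],
)
def test_roll_factor_from_step_values(Sl, f, expected):
    assert roll_factor_from_step(Sl, f) == pytest.approx(expected, rel=1e-12)


def test_roll_factor_singular_at_foot_length():
    with pytest.raises(SingularStepError):
        roll_factor_from_step(0.25, 0.25)
    with pytest.raises(SingularStepError):
        roll_factor_from_step(0.25 + 1e-13, 0.25)


def test_step_length_values_and_pole():
    assert step_length_from_rho(2.0, 0.25) == pytest.approx(0.50, rel=1e-12)
    assert step_length_from_rho(1.0 + 0.25 / 0.35, 0.25) == pytest.approx(0.60, rel=1e-10)
    assert step_length_from_rho(1.0 + 1e-9, 0.25) > 1e7
    with pytest.raises(DomainError):
        step_length_from_rho(1.0, 0.25)


@given(rho=st.floats(1.0 + 1e-6, 2.5), f=st.floats(0.05, 0.5))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_step_roll_factor_round_trip(rho, f):
    sl = step_length_from_rho(rho, f)
    assert roll_factor_from_step(sl, f) == pytest.approx(rho, rel=1e-10)


def test_round_trip_on_step_lengths():
    f = 0.25
    for sl in np.linspace(2 * f + 1e-3, 1.5, 50):
        assert step_length_from_rho(roll_factor_from_step(sl, f), f) == pytest.approx(
            sl, rel=1e-10
        )


def test_natural_frequency_and_period():
    # rho = 1 reduces to the inherent pendulum
    assert natural_frequency(1.0, 0.9) == pytest.approx(math.sqrt(9.81 / 0.9), rel=1e-12)
    assert swing_period(1.0, 0.9) == pytest.approx(inherent_period(0.9), rel=1e-12)
    w = natural_frequency(1.6, 0.9)
    assert w == pytest.approx(math.sqrt(0.4 * 9.81 / 0.9), rel=1e-12)
    assert swing_period(1.6, 0.9) == pytest.approx(1.0 / w, rel=1e-12)
    assert swing_period(2.0 - 1e-9, 0.9) > 1e3
    with pytest.raises(DomainError):
        natural_frequency(2.0, 0.9)


def test_cadence_hand_value():
    # 0.8*sqrt(0.4)/sqrt(0.9/9.81) steps/s = 100.23 steps/min
    assert cadence_per_second(1.6, 0.9, 0.1) == pytest.approx(1.67045, abs=1e-4)
    assert cadence(1.6, 0.9, 0.1) == pytest.approx(100.23, abs=0.01)


def test_cadence_monotone_and_limits():
    rhos = np.linspace(1.01, 1.99, 300)
    nc = cadence(rhos, 0.9, 0.1)
    assert np.all(np.diff(nc) < 0)
    assert cadence(1.6, 0.9, 0.4999999) == pytest.approx(0.0, abs=1e-3)
    assert cadence(2.0 - 1e-12, 0.9, 0.1) == pytest.approx(0.0, abs=1e-3)
    with pytest.raises(DomainError):
        cadence(1.6, 0.9, 0.5)
    with pytest.raises(DomainError):
        cadence(2.0, 0.9, 0.1)


def test_gait_speed_hand_value_and_limits():
    assert gait_speed(1.6, 0.25, 0.9, 0.1) == pytest.approx(1.1136, abs=1e-3)
    assert gait_speed(1.6, 0.25, 0.9, 0.4999999) == pytest.approx(0.0, abs=1e-4)
    assert gait_speed(2.0 - 1e-12, 0.25, 0.9, 0.1) == pytest.approx(0.0, abs=1e-3)


def test_vertical_excursion_values_and_monotonicity():
    assert vertical_excursion(2.0, 0.25, 0.9) == pytest.approx(0.25**2 / (4 * 0.9), rel=1e-12)
    assert vertical_excursion(1.5, 0.25, 0.9) == pytest.approx(0.052083, abs=1e-6)
    rhos = np.linspace(1.01, 1.99, 300)
    dh = vertical_excursion(rhos, 0.25, 0.9)
    assert np.all(np.diff(dh) < 0)
    assert vertical_excursion(1.4, 0.25, 0.9) > vertical_excursion(1.8, 0.25, 0.9)
    with pytest.raises(DomainError):
        vertical_excursion(1.0, 0.25, 0.9)


def test_speed_identity_random_tuples(rng):
    """V equals (steps/s) x Sl to 1e-10 relative for random valid tuples."""
    n = 10_000
    rho = rng.uniform(1.0 + 1e-6, 2.0 - 1e-6, n)
    f = rng.uniform(0.1, 0.4, n)
    L = rng.uniform(0.6, 1.2, n)
    xi = rng.uniform(0.0, 0.49, n)
    v = gait_speed(rho, f, L, xi)
    v_id = cadence_per_second(rho, L, xi) * step_length_from_rho(rho, f)
    assert np.max(np.abs(v - v_id) / v) < 1e-10


def test_band_partition_grid():
    """Computed rho falls in exactly one band, matching direct Sl/f inequalities."""
    f = 0.25
    for ratio in np.linspace(0.01, 10.0, 500):
        sl = ratio * f
        if abs(sl - f) < 1e-9:
            continue
        rho = roll_factor_from_step(sl, f)
        bands = [rho < 1.0 or rho == 1.0, 1.0 < rho < 2.0, rho >= 2.0]
        assert sum(bands) == 1
        if sl > 2 * f:
            assert 1.0 < rho < 2.0
        elif sl > f:
            assert rho >= 2.0
        else:
            assert rho < 1.0


def test_predict_gait_bundle(profile, constants):
    p = predict_gait(1.6, profile, constants)
    assert p.step_length == pytest.approx(0.6667, abs=1e-4)
    assert p.cadence == pytest.approx(100.23, abs=0.01)
    assert p.speed == pytest.approx(1.1136, abs=1e-3)
    assert p.speed == pytest.approx(p.cadence / 60.0 * p.step_length, rel=1e-10)
    # round trip through the step-length map
    sl = 0.62
    p2 = predict_gait(roll_factor_from_step(sl, profile.f), profile, constants)
    assert p2.step_length == pytest.approx(sl, rel=1e-10)


def test_predict_gait_domain_scan(profile, constants):
    for rho in np.linspace(1.01, 1.99, 99):
        p = predict_gait(rho, profile, constants)
        for v in p.as_dict().values():
            assert np.isfinite(v) and v > 0
    for rho in (1.0, 2.0, 0.5, 2.5):
        with pytest.raises(DomainError):
            predict_gait(rho, profile, constants)


def test_profile_validation():
    with pytest.raises(GeometryError):
        AnthropometricProfile(L=0.9, f=0.25, l1=0.5, l2=0.5)  # l1+l2 != L
    with pytest.raises(GeometryError):
        AnthropometricProfile(L=0.9, f=0.25, r=0.9)  # r >= L
    with pytest.raises(GeometryError):
        AnthropometricProfile(L=-1.0, f=0.25)
    with pytest.warns(UserWarning):
        AnthropometricProfile(L=0.9, f=0.95)  # foot longer than leg
    with pytest.raises(GeometryError):
        ModelConstants(xi=0.5)
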