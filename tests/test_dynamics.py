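"""Single-support dynamics: closed-form oracle, RK4 order, geometry."""

import math

import numpy as np
import pytest

from arcgait import (
    DomainError,
    IntegrationError,
    PendulumState,
    com_height,
    geometric_offsets,
    linearized_acceleration,
    moment_balance_residual,
    simulate_single_support,
    vertical_excursion,
    vertical_excursion_geometric,
)
from arcgait.profiles import AnthropometricProfile, ModelConstants


def closed_form(theta0, thetadot0, rho, L, g, t):
    """Independent cosh/sinh solution of theta'' = (g/L)(2-rho) theta."""
    w = math.sqrt((g / L) * (2.0 - rho))
    t = np.asarray(t, dtype=float)
    return theta0 * np.cosh(w * t) + (thetadot0 / w) * np.sinh(w * t)


@pytest.mark.parametrize(
    "theta, rho, expected",
    [(0.0, 1.6, 0.0), (0.1, 1.6, 0.4 * (9.81 / 0.9) * 0.1), (0.3, 2.0, 0.0)],
)
def test_linearized_acceleration_values(theta, rho, expected):
    assert linearized_acceleration(theta, rho, 0.9) == pytest.approx(expected, abs=1e-12)


def test_simulation_matches_closed_form(profile, constants):
    traj = simulate_single_support(
        PendulumState(theta_r=0.05), 1.6, profile, constants, duration=0.5, dt=1e-3
    )
    ref = closed_form(0.05, 0.0, 1.6, profile.L, constants.g, traj.t)
    assert np.max(np.abs(traj.theta - ref)) < 1e-6
    # COM height from the exact geometry at every sample
    assert traj.h == pytest.approx(com_height(traj.theta, 0.0, profile), abs=0)


def test_rest_at_equilibrium(profile, constants):
    traj = simulate_single_support(
        PendulumState(theta_r=0.0), 1.6, profile, constants, duration=0.3, dt=1e-3
    )
    assert np.max(np.abs(traj.theta)) == 0.0
    assert traj.h == pytest.approx(np.full_like(traj.h, profile.L), abs=1e-12)
    assert traj.dh_peak == pytest.approx(0.0, abs=1e-12)


def test_rk4_fourth_order_convergence(profile, constants):
    """Halving dt shrinks the closed-form error ~16x (4th order)."""
    errs = []
    for dt in (0.02, 0.01, 0.005):
        traj = simulate_single_support(
            PendulumState(theta_r=0.05, theta_dot=0.1),
            1.6,
            profile,
            constants,
            duration=0.5,
            dt=dt,
        )
        ref = closed_form(0.05, 0.1, 1.6, profile.L, constants.g, traj.t)
        errs.append(np.max(np.abs(traj.theta - ref)))
    orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
    assert np.all(orders > 3.8)


def test_simulation_domain_and_errors(profile, constants):
    with pytest.raises(DomainError):
        simulate_single_support(PendulumState(0.05), 2.0, profile, constants)
    with pytest.raises(IntegrationError):
        simulate_single_support(PendulumState(0.05), 1.6, profile, constants, duration=0.5, dt=0.0)
    with pytest.raises(IntegrationError):
        PendulumState(theta_r=float("nan"))


def test_com_height_hand_value():
    p = AnthropometricProfile(L=0.9, f=0.25, l1=0.45, l2=0.45, r=0.05)
    expected = 0.45 * math.cos(0.2) + 0.40 * math.cos(0.2) + 0.05
    assert com_height(0.2, 0.0, p) == pytest.approx(expected, rel=1e-12)
    assert com_height(0.0, 0.0, p) == pytest.approx(p.L, abs=1e-15)
    assert vertical_excursion_geometric(0.0, 0.0, p) == 0.0
    # cosine parity in theta when the knee is straight
    assert vertical_excursion_geometric(0.15, 0.0, p) == pytest.approx(
        vertical_excursion_geometric(-0.15, 0.0, p), rel=1e-12
    )


def test_geometric_offsets_upright_and_sign(profile):
    g0 = geometric_offsets(PendulumState(0.0, 0.0), profile, 1.6)
    assert g0.x_off == 0.0
    assert g0.y_off == g0.Liv > 0
    gpos = geometric_offsets(PendulumState(0.1, 0.0), profile, 1.6)
    assert gpos.x_off < 0  # COM ahead of contact under the printed convention


def test_geometric_offsets_reduce_to_simple_pendulum():
    """With no rocker and straight knee the linearized offset matches the
    exact trigonometric offset -L sin(rho theta) to third order."""
    p = AnthropometricProfile(L=0.9, f=0.25, r=0.0)
    rho = 1.3
    for theta in (0.02, 0.05, 0.1, 0.2):
        geom = geometric_offsets(PendulumState(theta, 0.0), p, rho, Liv=p.L)
        exact = -p.L * math.sin(rho * theta)
        assert abs(geom.x_off - exact) < (rho * theta) ** 3


def test_excursion_formulas_agree_within_5pct():
    """Exact two-link droop at the half-step angle vs the closed form,
    with the rocker radius tied to rho through the 1-DOF relation."""
    L = 0.9
    for rho in np.linspace(1.4, 1.8, 9):
        for f_over_L in np.linspace(0.2, 0.35, 7):
            f = f_over_L * L
            r = L * (1.0 - 1.0 / rho)
            p = AnthropometricProfile(L=L, f=f, r=r)
            theta = (rho * f / (rho - 1.0)) / (2.0 * L)  # half-step angle
            dh_geom = vertical_excursion_geometric(theta, 0.0, p)
            dh_simple = vertical_excursion(rho, f, L)
            assert dh_geom == pytest.approx(dh_simple, rel=0.05)


def test_energy_exchange_on_symmetric_arc(profile, constants):
    """COM is highest where the angular speed is lowest (pendular energy
    exchange), on an arc that crosses upright."""
    traj = simulate_single_support(
        PendulumState(theta_r=-0.12, theta_dot=0.8),
        1.6,
        profile,
        constants,
        duration=0.4,
        dt=1e-3,
    )
    assert int(np.argmax(traj.h)) == int(np.argmin(np.abs(traj.theta_dot)))


def test_moment_residual_scales_linearly(profile, constants):
    """The linearized dynamics satisfy the moment balance only to leading
    order; the residual should scale ~linearly with amplitude."""
    res = []
    for amp in (0.02, 0.04):
        traj = simulate_single_support(
            PendulumState(theta_r=amp), 1.6, profile, constants, duration=0.3, dt=1e-3
        )
        r = moment_balance_residual(traj, profile, 1.6, constants)
        assert np.all(np.isfinite(r))
        res.append(np.max(np.abs(r[5:-5])))
    assert res[1] / res[0] == pytest.approx(2.0, rel=0.1)
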