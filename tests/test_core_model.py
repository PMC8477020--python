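"""Unit and property tests of the mechanistic gland model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ptgtwin as pt
from ptgtwin.core_model import (
    EnvironmentInputs,
    PTGParameters,
    PTGState,
    advance_slow,
    evaluate_rhs,
    integrate_fast,
    secretion_activation,
    steady_state,
)
from ptgtwin.errors import (
    DegenerateStateError,
    DomainError,
    UnitTagError,
)

from conftest import draw_params


# ---------------------------------------------------------------------------
# parameters & state invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("field,value", [
    ("d0", 0.0), ("p_rate", -1.0), ("k_cl", 0.0), ("h", 0.5),
    ("eps_d", 1.0), ("k_ca_setpoint", 0.5), ("p_opt", 3.5),
])
def test_parameter_invariants_rejected(default_params, field, value):
    with pytest.raises(DomainError):
        default_params.replace(**{field: value})


def test_state_requires_positive_gland_mass():
    with pytest.raises(DegenerateStateError):
        PTGState(q=0.0, a=0.0, s=1.0, c=1.0, t=0.0, t_unit="min")
    with pytest.raises(DomainError):
        PTGState(q=1.0, a=0.0, s=-1.0, c=1.0, t=0.0, t_unit="min")
    with pytest.raises(UnitTagError):
        PTGState(q=1.0, a=0.0, s=1.0, c=1.0, t=0.0, t_unit="hours")


# ---------------------------------------------------------------------------
# secretion activation
# ---------------------------------------------------------------------------

def test_activation_half_maximal_at_setpoint_exactly(config, rng):
    for _ in range(20):
        p = draw_params(config, rng)
        assert secretion_activation(p.k_ca_setpoint, p) == 0.5


def test_activation_limits_and_example(default_params):
    p = default_params
    assert secretion_activation(1e-9, p) == pytest.approx(1.0)
    assert secretion_activation(50.0, p) == pytest.approx(0.0, abs=1e-10)
    # hand evaluation at ca = 1.1 * set-point with h = 7
    expected = 1.0 / (1.0 + 1.1 ** 7)
    got = secretion_activation(1.1 * p.k_ca_setpoint, p)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(0.3391, abs=5e-4)


@given(ca=st.floats(0.6, 1.9), ca2=st.floats(0.6, 1.9))
def test_activation_strictly_decreasing(ca, ca2, default_params):
    if ca == ca2:
        return
    lo, hi = sorted([ca, ca2])
    assert secretion_activation(lo, default_params) > \
        secretion_activation(hi, default_params)


def test_activation_rejects_nonpositive_calcium(default_params):
    with pytest.raises(DomainError):
        secretion_activation(0.0, default_params)
    with pytest.raises(DomainError):
        secretion_activation(np.array([1.1, -0.2]), default_params)


# ---------------------------------------------------------------------------
# RHS and steady state
# ---------------------------------------------------------------------------

def test_rhs_vanishes_at_steady_state(config, rng):
    for _ in range(10):
        p = draw_params(config, rng)
        ca, phos = rng.uniform(1.0, 1.35), rng.uniform(1.2, 2.2)
        ss = steady_state(ca, phos, 0, p.gland_size0, p)
        d = evaluate_rhs(ss, (ca, phos, 0.0), p, mode="fast")
        scale = np.array([ss.q, ss.a, ss.s, ss.c])
        assert np.all(np.abs(np.asarray(d)) <= 1e-10 * np.maximum(scale, 1))


def test_calcitriol_switch_lowers_synthesis_by_linear_term(default_params):
    p = default_params
    ss = steady_state(1.15, 1.8, 0, 1.0, p)
    d_off = evaluate_rhs(ss, (1.15, 1.8, 0.0), p, mode="fast")
    d_on = evaluate_rhs(ss, (1.15, 1.8, 1.0), p, mode="fast")
    psi = 1.0 + p.alpha_p * (1.8 - p.p_opt) / p.p_opt
    expected_drop = p.p_rate * (ss.q + ss.a) * psi * p.eps_d
    assert d_off[2] - d_on[2] == pytest.approx(expected_drop, rel=1e-12)


def test_rhs_rejects_degenerate_gland():
    st_obj = type("S", (), {"q": 0.0, "a": 0.0, "s": 1.0, "c": 1.0})()
    p = PTGParameters(k_ca_setpoint=1.15, p_opt=1.5, gland_size0=1.0,
                      d0=0.1, p_rate=3.7e5, k_cl=0.25)
    with pytest.raises(DegenerateStateError):
        evaluate_rhs(st_obj, (1.1, 1.5, 0.0), p, mode="fast")


def test_plasma_ipth_falls_after_calcium_step_up(default_params):
    """A calcium step above the set-point must lower iPTH once the stored
    pool transient settles."""
    p = default_params
    ss = steady_state(p.k_ca_setpoint, p.p_opt, 0, 1.0, p)
    traj = integrate_fast(ss, EnvironmentInputs.constant(
        1.15 * p.k_ca_setpoint, p.p_opt, 0), p, 60.0)
    assert traj["c"].iloc[-1] < ss.c
    late = traj[traj["t_min"] >= 30.0]["c"].to_numpy()
    assert np.all(np.diff(late) <= 1e-9)


def test_steady_state_monotone_in_calcium_and_phosphate(default_params):
    p = default_params
    grid = np.arange(0.9, 1.51, 0.1)
    c = [steady_state(ca, p.p_opt, 0, 1.0, p).c for ca in grid]
    assert np.all(np.diff(c) < 0)
    phos_grid = np.arange(1.0, 2.6, 0.25)
    cp = [steady_state(p.k_ca_setpoint, ph, 0, 1.0, p).c
          for ph in phos_grid]
    assert np.all(np.diff(cp) >= 0)


def test_steady_state_guards_zero_activation(default_params):
    """In the no-activation limit secretion stops: stored pool balances
    production against degradation only and plasma iPTH vanishes."""
    p = default_params
    phi_zero = pt.ResponseFunctions(phi=lambda ca, pp: np.zeros_like(
        np.asarray(ca, dtype=float)))
    ss = steady_state(1.3, p.p_opt, 0, 1.0, p, responses=phi_zero)
    assert ss.c == 0.0
    assert ss.s == pytest.approx(p.p_rate * 1.0 / p.d0, rel=1e-12)


# ---------------------------------------------------------------------------
# fast integration
# ---------------------------------------------------------------------------

def test_zero_duration_returns_initial_state(default_params):
    ss = steady_state(1.15, 1.5, 0, 1.0, default_params)
    traj = integrate_fast(ss, EnvironmentInputs.constant(1.15, 1.5, 0),
                          default_params, 0.0)
    assert len(traj) == 1
    assert traj["c"].iloc[0] == ss.c


def test_fixed_point_invariance_over_session(default_params):
    p = default_params
    ss = steady_state(p.k_ca_setpoint, p.p_opt, 0, 1.0, p)
    traj = integrate_fast(ss, EnvironmentInputs.constant(
        p.k_ca_setpoint, p.p_opt, 0), p, 240.0)
    assert np.max(np.abs(traj["c"] / ss.c - 1)) < 1e-3


def test_integration_rejects_out_of_domain_inputs(default_params):
    ss = steady_state(1.15, 1.5, 0, 1.0, default_params)
    bad = EnvironmentInputs.constant(2.5, 1.5, 0)
    with pytest.raises(DomainError):
        integrate_fast(ss, bad, default_params, 10.0)


def test_trajectory_nonnegative_under_random_inputs(config, rng):
    for _ in range(5):
        p = draw_params(config, rng)
        t_knots = np.linspace(0, 240, 9)
        ca_knots = rng.uniform(1.0, 1.5, 9)
        inputs = EnvironmentInputs(
            ca=lambda t: float(np.interp(t, t_knots, ca_knots)),
            phos=lambda t: 1.6, calcitriol=lambda t: 0.0)
        ss = steady_state(ca_knots[0], 1.6, 0, p.gland_size0, p)
        start = PTGState(q=ss.q, a=ss.a, s=ss.s * 0.5, c=ss.c * 1.5,
                         t=0.0, t_unit="min")
        traj = integrate_fast(start, inputs, p, 240.0)
        assert (traj[["q", "a", "s", "c"]].to_numpy() >= 0).all()


def test_mass_accounting_without_production(default_params):
    """With production off, hormone leaving the stored pool is exactly
    split between secretion and intracellular degradation."""
    p = default_params.replace(p_rate=1e-12)
    start = PTGState(q=0.5, a=0.5, s=1e6, c=100.0, t=0.0, t_unit="min")
    traj = integrate_fast(start, EnvironmentInputs.constant(1.1, 1.5, 0),
                          p, 120.0)
    phi = secretion_activation(1.1, p)
    frac = traj["a"] / (traj["q"] + traj["a"])
    secreted = np.trapezoid(p.sigma_max * phi * frac * traj["s"],
                            traj["t_min"])
    degraded = np.trapezoid(p.d0 * (1 - phi) * traj["s"], traj["t_min"])
    lost = start.s - traj["s"].iloc[-1]
    assert secreted + degraded == pytest.approx(lost, rel=1e-2)


# ---------------------------------------------------------------------------
# slow engine
# ---------------------------------------------------------------------------

def test_balanced_growth_at_setpoint(default_params):
    p = default_params
    st0 = PTGState(q=0.5, a=0.5, s=1.0, c=1.0, t=0.0, t_unit="day")
    daily = np.tile([p.k_ca_setpoint, p.p_opt, 0.0], (180, 1))
    traj = advance_slow(st0, daily, p)
    assert np.ptp(traj["gland_mass"]) == pytest.approx(0.0, abs=1e-12)
    assert np.ptp(traj["c"]) == pytest.approx(0.0, abs=1e-9)


def test_chronic_hypocalcemia_grows_gland_and_raises_ipth(default_params):
    p = default_params
    st0 = PTGState(q=0.5, a=0.5, s=1.0, c=1.0, t=0.0, t_unit="day")
    daily = np.tile([0.9 * p.k_ca_setpoint, p.p_opt, 0.0], (180, 1))
    traj = advance_slow(st0, daily, p)
    assert np.all(np.diff(traj["gland_mass"]) >= 0)
    assert np.all(np.diff(traj["c"]) >= -1e-12)
    assert traj["gland_mass"].iloc[-1] > 1.0


def test_slow_requires_day_tagged_state(default_params):
    st0 = PTGState(q=0.5, a=0.5, s=1.0, c=1.0, t=0.0, t_unit="min")
    with pytest.raises(UnitTagError):
        advance_slow(st0, np.tile([1.15, 1.5, 0.0], (5, 1)), default_params)


def test_gland_floor_flagged_on_collapse(default_params):
    """Sustained hypercalcemia shrinks the gland; collapse clamps at the
    floor and raises the warning flag."""
    p = default_params.replace(mu=0.9, lambda_max=0.001)
    st0 = PTGState(q=1e-5, a=1e-5, s=1.0, c=1.0, t=0.0, t_unit="day")
    daily = np.tile([1.4, p.p_opt, 0.0], (60, 1))
    traj = advance_slow(st0, daily, p)
    assert traj.attrs["gland_floor_hit"]
    assert traj["gland_mass"].min() >= 1e-6
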