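"""Tests of session simulation, scenarios and the weekly-median rule."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

import ptgtwin as pt
from ptgtwin.core_model import steady_state
from ptgtwin.errors import ConfigError, DomainError, InsufficientDataError
from ptgtwin.prediction import (
    DialysisSession,
    ScenarioSpec,
    apply_scenario,
    interpolate_ica,
    peridialytic_change,
    predict_longterm,
    simulate_session,
    weekly_median,
)

SDATE = date(2021, 6, 15)


def _session(points, duration=240.0, **kw):
    return DialysisSession(patient_id="px", session_date=SDATE,
                           ica_points=points, duration_min=duration, **kw)


# ---------------------------------------------------------------------------
# session container and interpolation
# ---------------------------------------------------------------------------

def test_session_validation():
    with pytest.raises(DomainError):
        _session(((10.0, 1.1), (240.0, 1.3)))        # missing t = 0
    with pytest.raises(DomainError):
        _session(((0.0, 1.1),))                      # single point
    with pytest.raises(DomainError):
        _session(((0.0, 1.1), (60.0, 1.2), (60.0, 1.25)))  # non-increasing
    with pytest.raises(DomainError):
        _session(((0.0, 0.4), (240.0, 1.3)))         # out of domain


def test_interpolation_through_nodes_and_midpoint():
    s = _session(((0.0, 1.08), (240.0, 1.32)))
    assert interpolate_ica(s, 0.0) == 1.08
    assert interpolate_ica(s, 240.0) == 1.32
    assert interpolate_ica(s, 120.0) == pytest.approx(1.20, rel=1e-12)
    # constant extension beyond the last measurement
    assert interpolate_ica(s, 250.0) == 1.32
    with pytest.raises(DomainError):
        interpolate_ica(s, -1.0)


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def test_flat_session_at_setpoint_changes_nothing(default_params):
    p = default_params
    s = _session(((0.0, p.k_ca_setpoint), (240.0, p.k_ca_setpoint)))
    pred = simulate_session(p, s, phos=p.p_opt)
    assert abs(pred.delta) < 0.01 * pred.pre


def test_calcium_loading_lowers_ipth_and_steeper_ramp_lowers_more(
        default_params):
    p = default_params
    ramp = _session(((0.0, 1.08), (240.0, 1.32)))
    steep = _session(((0.0, 1.08), (240.0, 1.40)))
    pred = simulate_session(p, ramp, phos=p.p_opt)
    pred2 = simulate_session(p, steep, phos=p.p_opt)
    assert pred.post < pred.pre
    assert pred2.delta_pct < pred.delta_pct


def test_same_calcium_course_different_patients_different_drops(
        default_params):
    """Two patients with near-identical intradialytic calcium can show
    very different absolute iPTH drops (set-point and scale differ)."""
    s = _session(((0.0, 1.08), (120.0, 1.25), (240.0, 1.32)))
    mild = default_params.replace(k_ca_setpoint=1.25, p_rate=8e5)
    blunted = default_params.replace(k_ca_setpoint=1.02, p_rate=1e5)
    d1 = simulate_session(mild, s, phos=mild.p_opt).delta
    d2 = simulate_session(blunted, s, phos=blunted.p_opt).delta
    assert d1 < d2 < 0
    assert abs(d1) > 3 * abs(d2)


def test_uniform_upscaling_of_calcium_never_raises_post(default_params):
    p = default_params
    base = _session(((0.0, 1.10), (120.0, 1.22), (240.0, 1.30)))
    post_prev = np.inf
    for scale in (1.0, 1.03, 1.06, 1.09):
        pts = tuple((t, v * scale) for t, v in base.ica_points)
        pred = simulate_session(p, _session(pts), phos=p.p_opt)
        assert pred.post <= post_prev + 1e-9
        post_prev = pred.post


def test_peridialytic_change_arithmetic():
    assert peridialytic_change(277.0, 51.0) == \
        pytest.approx((-226.0, -81.58844765342961))
    assert peridialytic_change(100.0, 100.0) == (0.0, 0.0)
    assert peridialytic_change(100.0, 25.0) == (-75.0, -75.0)
    with pytest.raises(DomainError):
        peridialytic_change(0.0, 10.0)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_scenario_parsing_and_validation():
    sc = ScenarioSpec.parse("ica:+10")
    assert sc.target == "ica" and sc.fractional_change == 0.10
    sc = ScenarioSpec.parse("phos:-25")
    assert sc.target == "phos" and sc.fractional_change == -0.25
    assert ScenarioSpec.parse("none").target == "none"
    with pytest.raises(ConfigError):
        ScenarioSpec.parse("urea:+10")
    with pytest.raises(ConfigError):
        ScenarioSpec("none", 0.1)
    with pytest.raises(ConfigError):
        ScenarioSpec("ica", 0.9)


def test_apply_scenario_perturbs_target_and_pins_other():
    idx = pd.Index([1, 2, 3], name="day")
    series = {"ica": pd.Series([1.20, 1.25, 1.30], index=idx),
              "phos": pd.Series([1.78, 1.90, 1.60], index=idx)}
    out = apply_scenario(series, ScenarioSpec("ica", 0.10))
    assert out["ica"].iloc[0] == pytest.approx(1.32)
    assert (out["phos"] == 1.78).all()
    out2 = apply_scenario(series, ScenarioSpec("phos", 0.25))
    assert out2["phos"].iloc[0] == pytest.approx(2.225)
    unchanged = apply_scenario(series, ScenarioSpec("none", 0.0))
    assert unchanged["ica"].equals(series["ica"])
    assert unchanged["phos"].equals(series["phos"])


def test_longterm_flat_at_setpoint_is_flat(default_params):
    p = default_params
    series = predict_longterm(p, None, ScenarioSpec("ica", 0.0),
                              baseline_ica=p.k_ca_setpoint,
                              baseline_phos=p.p_opt, horizon_days=180)
    ss = steady_state(p.k_ca_setpoint, p.p_opt, 0, p.gland_size0, p)
    assert len(series) == 180
    assert np.max(np.abs(series / ss.c - 1)) < 1e-9


def test_longterm_scenario_ordering(default_params):
    p = default_params
    kw = dict(baseline_ica=1.17, baseline_phos=1.9, horizon_days=180)
    up = predict_longterm(p, None, ScenarioSpec("ica", 0.10), **kw)
    base = predict_longterm(p, None, ScenarioSpec("ica", 0.0), **kw)
    down = predict_longterm(p, None, ScenarioSpec("ica", -0.10), **kw)
    assert up.iloc[-1] < base.iloc[-1] < down.iloc[-1]
    pdown = predict_longterm(p, None, ScenarioSpec("phos", -0.25), **kw)
    pup = predict_longterm(p, None, ScenarioSpec("phos", 0.25), **kw)
    assert pdown.iloc[-1] <= base.iloc[-1] <= pup.iloc[-1]


def test_longterm_without_labs_needs_scenario(default_params):
    with pytest.raises(InsufficientDataError):
        predict_longterm(default_params, pd.DataFrame(
            columns=["day", "analyte", "value"]),
            ScenarioSpec("none", 0.0), 1.17, 1.8)


def test_longterm_follows_postindex_labs(default_params):
    labs = pd.DataFrame({"day": [30, 90], "analyte": ["ica", "ica"],
                         "value": [1.10, 1.30]})
    series = predict_longterm(default_params, labs, ScenarioSpec("none", 0.0),
                              baseline_ica=1.17, baseline_phos=1.8,
                              horizon_days=120)
    # forward-fill: lower calcium raises iPTH after day 30, higher lowers
    assert series.loc[60] > series.loc[20]
    assert series.loc[120] < series.loc[60]


# ---------------------------------------------------------------------------
# weekly median
# ---------------------------------------------------------------------------

def test_weekly_median_conventions():
    s = pd.Series([90.0, 98.0, 104.0, 110.0, 120.0],
                  index=pd.Index([176, 178, 180, 182, 190], name="day"))
    assert weekly_median(s, 180) == 104.0           # odd count in window
    s2 = pd.Series([98.0, 110.0], index=pd.Index([179, 181], name="day"))
    assert weekly_median(s2, 180) == 104.0          # mean of middle pair
    s3 = pd.Series([98.0], index=pd.Index([183, ], name="day"))
    assert weekly_median(s3, 180) == 98.0           # singleton
    with pytest.raises(InsufficientDataError):
        weekly_median(s3, 100)
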