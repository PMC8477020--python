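"""Short-term session simulation and the 6-month scenario engine.

Short term: the fitted gland model is driven by the *measured*
intradialytic ionized-calcium course (piecewise-linear interpolation
between draws) to predict the peridialytic iPTH drop of one treatment.

Long term: daily iCa/phosphate inputs — either forward-filled from the
patient's post-index labs or constant scenario perturbations of the index
baselines (±10% iCa, ±25% phosphate) — drive the quasi-steady slow engine
for up to 180 days. Because labs rarely fall on the exact follow-up day,
the headline long-term prediction is the median of the predicted daily
values in the week around the reference measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core_model import (
    CA_DOMAIN,
    EnvironmentInputs,
    PTGParameters,
    PTGState,
    advance_slow,
    integrate_fast,
    steady_state,
)
from .errors import ConfigError, DomainError, InsufficientDataError

SCENARIO_TARGETS = ("ica", "phos", "none")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DialysisSession:
    """Timed intradialytic iCa measurements with optional pre/post iPTH."""

    patient_id: str
    session_date: object                  # datetime.date
    ica_points: tuple                     # ((minute, mmol/l), ...), >= 2
    duration_min: float = 240.0
    ipth_pre: Optional[float] = None
    ipth_post: Optional[float] = None

    def __post_init__(self):
        pts = tuple((float(t), float(v)) for t, v in self.ica_points)
        object.__setattr__(self, "ica_points", pts)
        if len(pts) < 2:
            raise DomainError("need >= 2 intradialytic iCa points")
        times = np.array([t for t, _ in pts])
        values = np.array([v for _, v in pts])
        if times[0] != 0.0:
            raise DomainError("first iCa point must be at t = 0")
        if np.any(np.diff(times) <= 0):
            raise DomainError("iCa measurement minutes must strictly increase")
        lo, hi = CA_DOMAIN
        if np.any(values <= lo) or np.any(values >= hi):
            raise DomainError("intradialytic iCa outside (0.5, 2.0) mmol/l")
        if self.duration_min <= 0:
            raise DomainError("duration_min must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.ica_points])

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.ica_points])


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual input perturbation for the long-term engine.

    ``fractional_change`` is a signed fraction applied multiplicatively to
    the target analyte from the index date on (e.g. +0.10 for a 10% iCa
    rise); the other analyte is held at its index baseline.
    """

    target: str = "none"                  # "ica" | "phos" | "none"
    fractional_change: float = 0.0
    horizon_days: int = 180

    def __post_init__(self):
        if self.target not in SCENARIO_TARGETS:
            raise ConfigError(f"unknown scenario target {self.target!r}")
        if self.target == "none" and self.fractional_change != 0.0:
            raise ConfigError("scenario 'none' requires fractional_change = 0")
        if abs(self.fractional_change) > 0.5:
            raise ConfigError("|fractional_change| must be <= 0.5")
        if self.horizon_days < 1:
            raise ConfigError("horizon_days must be >= 1")

    @classmethod
    def parse(cls, text: str, horizon_days: int = 180) -> "ScenarioSpec":
        """Parse the ``target:signed-percent`` syntax, e.g. ``ica:+10``."""
        text = text.strip().lower()
        if text == "none":
            return cls("none", 0.0, horizon_days)
        try:
            target, pct = text.split(":")
            return cls(target, float(pct) / 100.0, horizon_days)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"cannot parse scenario {text!r}; expected "
                              "e.g. 'ica:+10', 'phos:-25' or 'none'") from exc


@dataclass(frozen=True)
class SessionPrediction:
    """Predicted minute-resolved iPTH course and peridialytic change."""

    trajectory: pd.DataFrame   # t_min, q, a, s, c
    pre: float                 # predicted iPTH at t = 0 (pg/ml)
    post: float                # predicted iPTH at end of treatment (pg/ml)

    @property
    def delta(self) -> float:
        return self.post - self.pre

    @property
    def delta_pct(self) -> float:
        return 100.0 * (self.post - self.pre) / self.pre


# ---------------------------------------------------------------------------
# short-term operations
# ---------------------------------------------------------------------------

def interpolate_ica(session: DialysisSession, t) -> float | np.ndarray:
    """Piecewise-linear iCa between draws, constant beyond the last draw."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    out = np.interp(t_arr, session.times, session.values)
    return float(out) if np.isscalar(t) else out


def simulate_session(params: PTGParameters, session: DialysisSession,
                     initial: Optional[PTGState] = None,
                     phos: Optional[float] = None, calcitriol: float = 0.0,
                     rtol: float = 1e-6, atol: float = 1e-9
                     ) -> SessionPrediction:
    """Simulate one dialysis treatment under the measured iCa course.

    Unless an explicit ``initial`` state is given (e.g. carried over from a
    long-term run), the patient starts at the fast-subsystem steady state
    for the first measured iCa and the most recent phosphate — a patient
    arriving at dialysis is assumed equilibrated to their pre-treatment
    milieu.
    """
    if phos is None:
        phos = params.p_opt
    if initial is None:
        initial = steady_state(session.values[0], phos, calcitriol,
                               params.gland_size0, params)
    inputs = EnvironmentInputs(ca=lambda t: interpolate_ica(session, t),
                               phos=lambda t: phos,
                               calcitriol=lambda t: calcitriol)
    traj = integrate_fast(initial, inputs, params, session.duration_min,
                          rtol=rtol, atol=atol)
    return SessionPrediction(trajectory=traj,
                             pre=float(traj["c"].iloc[0]),
                             post=float(traj["c"].iloc[-1]))


def peridialytic_change(pre: float, post: float) -> tuple[float, float]:
    """Post-minus-pre iPTH change, absolute (pg/ml) and as percent of pre."""
    if pre <= 0:
        raise DomainError("pre-dialysis iPTH must be > 0")
    absolute = post - pre
    return absolute, 100.0 * absolute / pre


# ---------------------------------------------------------------------------
# long-term operations
# ---------------------------------------------------------------------------

def apply_scenario(series: Mapping[str, pd.Series], scenario: ScenarioSpec
                   ) -> dict[str, pd.Series]:
    """Perturb dated analyte series according to a scenario.

    The targeted analyte is multiplied by ``1 + fractional_change`` from
    the index date onward; the other analyte is pinned at its index-date
    baseline (first value), so each scenario isolates the effect of one
    electrolyte. ``none`` returns the series unchanged.
    """
    for name in series:
        if name not in ("ica", "phos"):
            raise ConfigError(f"unknown analyte {name!r} in series")
        if len(series[name]) == 0:
            raise DomainError("analyte series must be nonempty")
    if scenario.target == "none":
        return {k: v.copy() for k, v in series.items()}
    if scenario.target not in series:
        raise ConfigError(f"scenario target {scenario.target!r} not in series")
    out = {}
    for name, s in series.items():
        if name == scenario.target:
            out[name] = s * (1.0 + scenario.fractional_change)
        else:
            out[name] = pd.Series(s.iloc[0], index=s.index, name=s.name)
    return out


def predict_longterm(params: PTGParameters, labs_post: pd.DataFrame,
                     scenario: ScenarioSpec,
                     baseline_ica: float, baseline_phos: float,
                     horizon_days: int = 180, calcitriol: float = 0.0,
                     gland_mass_start: Optional[float] = None) -> pd.Series:
    """Daily predicted iPTH for ``horizon_days`` after the index date.

    Under ``scenario="none"`` the engine is driven by the patient's actual
    post-index labs (``labs_post`` with columns ``day, analyte, value``;
    day > 0), forward-filled from the index baselines. Under an active
    scenario, both analytes are held constant at the index baselines with
    the targeted one scaled by the scenario fraction — isolating the
    effect of a sustained change of a single electrolyte.

    Returns a Series indexed by day 1..horizon (pg/ml).
    """
    if horizon_days < 1:
        raise DomainError("horizon_days must be >= 1")
    days = np.arange(1, horizon_days + 1)
    const_idx = pd.Index(days, name="day")

    if scenario.target == "none":
        if labs_post is None or len(labs_post) == 0 or \
                not (labs_post["analyte"] == "ica").any():
            raise InsufficientDataError(
                "scenario 'none' needs >= 1 post-index iCa measurement")
        series = {}
        for analyte, base in (("ica", baseline_ica), ("phos", baseline_phos)):
            rows = labs_post[labs_post["analyte"] == analyte]
            obs_days = np.concatenate([[0.0], rows["day"].to_numpy(float)])
            obs_vals = np.concatenate([[base], rows["value"].to_numpy(float)])
            series[analyte] = pd.Series(
                _ffill(days, obs_days, obs_vals), index=const_idx)
    else:
        series = {"ica": pd.Series(baseline_ica, index=const_idx),
                  "phos": pd.Series(baseline_phos, index=const_idx)}
    series = apply_scenario(series, scenario)

    g0 = params.gland_size0 if gland_mass_start is None else gland_mass_start
    state0 = PTGState(q=g0 / 2, a=g0 / 2, s=1.0, c=1.0, t=1.0, t_unit="day")
    daily = np.column_stack([series["ica"].to_numpy(),
                             series["phos"].to_numpy(),
                             np.full(len(days), float(calcitriol))])
    traj = advance_slow(state0, daily, params)
    return pd.Series(traj["c"].to_numpy(), index=const_idx, name="ipth_pred")


def _ffill(days, obs_days, obs_vals):
    order = np.argsort(obs_days, kind="stable")
    od, ov = np.asarray(obs_days)[order], np.asarray(obs_vals)[order]
    idx = np.searchsorted(od, days, side="right") - 1
    return ov[np.clip(idx, 0, len(ov) - 1)]


def weekly_median(daily_series: pd.Series, reference_day: float,
                  halfwidth_days: int = 3) -> float:
    """Median predicted iPTH in the week around the reference measurement.

    The window is ``reference_day ± halfwidth_days`` (7 days by default);
    even counts use the mean of the two middle values (pandas median).
    """
    idx = np.asarray(daily_series.index, dtype=float)
    mask = (idx >= reference_day - halfwidth_days) & \
           (idx <= reference_day + halfwidth_days)
    if not mask.any():
        raise InsufficientDataError(
            f"no predicted values within ±{halfwidth_days} days of "
            f"day {reference_day}")
    return float(np.median(daily_series.to_numpy()[mask]))
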