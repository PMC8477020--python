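"""Patient-level individualization of the gland model.

Estimates the patient-specific parameter set (calcium and phosphate
set-points, gland size, intracellular degradation rate, production scale)
from six months of routine pre-assessment labs, dialysis vintage and the
calcitriol-therapy flag.

Identifiability is handled explicitly:

* the production scale is *anchored* so that the model's steady state at
  the patient's set-points reproduces the earliest in-window iPTH; the
  optimizer adjusts a bounded multiplicative offset around that anchor;
* gland size enters the anchored observable only through the vintage
  prior (the anchor absorbs its scale), so it is prior-determined;
* plasma clearance cannot be identified from sparse quasi-steady labs at
  all (it cancels exactly against the anchor) and is held at the
  population value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import core_model
from .core_model import PTGParameters, PTGState, advance_slow
from .errors import (
    DomainError,
    InsufficientDataError,
    NonConvergenceError,
    NotIndividualizableError,
)

ANALYTE_UNITS = {"ica": "mmol/l", "phos": "mmol/l", "ipth": "pg/ml"}

#: order of the free parameter vector passed to the optimizer
FREE_PARAM_NAMES = ("k_ca_setpoint", "p_opt", "gland_size0", "d0",
                    "p_rate_offset")

_FAILURE_RESIDUAL = 1e3


# ---------------------------------------------------------------------------
# records and fitting dataset
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """Metadata plus longitudinal labs for one patient."""

    patient_id: str
    vintage_days: float
    calcitriol: int
    calcimimetic: int
    assessment_date: Date
    labs: pd.DataFrame  # columns: date, analyte, value, unit

    def __post_init__(self):
        if self.vintage_days < 0:
            raise DomainError("vintage_days must be >= 0")
        if self.calcitriol not in (0, 1) or self.calcimimetic not in (0, 1):
            raise DomainError("therapy flags must be 0 or 1")
        required = {"date", "analyte", "value", "unit"}
        if not required.issubset(self.labs.columns):
            raise DomainError(f"labs must have columns {sorted(required)}")
        labs = self.labs.copy()
        bad = ~labs["analyte"].isin(ANALYTE_UNITS)
        if bad.any():
            raise DomainError(
                f"unknown analytes: {sorted(labs.loc[bad, 'analyte'].unique())}")
        for analyte, unit in ANALYTE_UNITS.items():
            rows = labs["analyte"] == analyte
            if (labs.loc[rows, "unit"] != unit).any():
                raise DomainError(f"{analyte} must be reported in {unit}")
        if (labs["value"] <= 0).any():
            raise DomainError("lab values must be strictly positive")
        labs["date"] = pd.to_datetime(labs["date"]).dt.date
        self.labs = labs.sort_values(["date", "analyte"],
                                     kind="stable").reset_index(drop=True)


@dataclass
class FitDataset:
    """Aligned daily input functions plus iPTH observations for one window.

    Days are integers relative to the assessment date (all negative: the
    window is ``[-window_days, -1]``, the assessment day itself being the
    prediction context, not fitting data).
    """

    days: np.ndarray          # window day axis, -W .. -1
    ca_daily: np.ndarray      # forward-filled daily iCa (mmol/l)
    phos_daily: np.ndarray    # forward-filled daily phosphate (mmol/l)
    cal_daily: np.ndarray     # calcitriol indicator per day
    obs_days: np.ndarray      # days with an iPTH observation
    obs_ipth: np.ndarray      # observed iPTH (pg/ml)
    ca_obs: np.ndarray        # raw in-window iCa draws (identifiability)
    phos_obs: np.ndarray
    vintage_days: float
    calcitriol: int

    @property
    def n_obs(self) -> int:
        return len(self.obs_ipth)

    @property
    def anchor_ipth(self) -> float:
        """Earliest in-window iPTH — the production-anchor target."""
        return float(self.obs_ipth[np.argmin(self.obs_days)])

    def daily_inputs(self) -> np.ndarray:
        return np.column_stack([self.ca_daily, self.phos_daily,
                                self.cal_daily])


@dataclass
class FitResult:
    """Outcome of one patient fit."""

    params: PTGParameters
    loss: float
    n_obs: int
    identifiable: dict
    diagnostics: dict
    gland_mass_at_assessment: float

    def free_vector(self) -> np.ndarray:
        return np.array([self.diagnostics["free_params"][n]
                         for n in FREE_PARAM_NAMES])


# ---------------------------------------------------------------------------
# window assembly
# ---------------------------------------------------------------------------

def _forward_fill_daily(days: np.ndarray, obs_days: np.ndarray,
                        obs_values: np.ndarray) -> np.ndarray:
    """Piecewise-constant-forward series on ``days`` from sparse draws.

    Days before the first draw take the first drawn value (a draw is the
    best available estimate of the recent past at window start).
    """
    order = np.argsort(obs_days, kind="stable")
    od, ov = np.asarray(obs_days)[order], np.asarray(obs_values)[order]
    idx = np.searchsorted(od, days, side="right") - 1
    return ov[np.clip(idx, 0, len(ov) - 1)]


def assemble_window(record: PatientRecord, window_days: int = 180
                    ) -> FitDataset:
    """Build the fitting dataset from labs inside the closed pre-assessment
    window ``[assessment - window_days, assessment - 1]``.

    Raises
    ------
    InsufficientDataError
        If the window contains no iPTH or no iCa observation.
    """
    if window_days <= 0:
        raise DomainError("window_days must be > 0")
    labs = record.labs.copy()
    rel = np.array([(d - record.assessment_date).days for d in labs["date"]])
    labs["rel_day"] = rel
    in_window = labs[(rel >= -window_days) & (rel <= -1)]

    by = {a: in_window[in_window["analyte"] == a] for a in ANALYTE_UNITS}
    if by["ipth"].empty:
        raise InsufficientDataError(
            f"{record.patient_id}: no iPTH in the {window_days}-day window")
    if by["ica"].empty:
        raise InsufficientDataError(
            f"{record.patient_id}: no iCa in the {window_days}-day window")

    days = np.arange(-window_days, 0)
    ca_daily = _forward_fill_daily(days, by["ica"]["rel_day"].to_numpy(),
                                   by["ica"]["value"].to_numpy())
    if by["phos"].empty:
        # no phosphate draws: hold a neutral mid-range level
        phos_daily = np.full(days.shape, 1.5)
        phos_obs = np.array([])
    else:
        phos_daily = _forward_fill_daily(days,
                                         by["phos"]["rel_day"].to_numpy(),
                                         by["phos"]["value"].to_numpy())
        phos_obs = by["phos"]["value"].to_numpy(dtype=float)
    cal_daily = np.full(days.shape, float(record.calcitriol))
    return FitDataset(
        days=days, ca_daily=ca_daily, phos_daily=phos_daily,
        cal_daily=cal_daily,
        obs_days=by["ipth"]["rel_day"].to_numpy(dtype=float),
        obs_ipth=by["ipth"]["value"].to_numpy(dtype=float),
        ca_obs=by["ica"]["value"].to_numpy(dtype=float),
        phos_obs=phos_obs,
        vintage_days=record.vintage_days, calcitriol=record.calcitriol)


# ---------------------------------------------------------------------------
# priors and anchoring
# ---------------------------------------------------------------------------

def vintage_prior(vintage_days: float, gamma: float = 0.3,
                  sd_frac: float = 0.5) -> tuple[float, float]:
    """Weak prior on gland mass, linear in vintage-years.

    Longer time on dialysis means more cumulative hyperplastic stimulus, so
    the prior mean grows from the healthy reference 1 by ``gamma`` per
    vintage-year; the sd is a fixed fraction of the mean (weak).
    """
    if vintage_days < 0:
        raise DomainError("vintage_days must be >= 0")
    mean = 1.0 + gamma * vintage_days / 365.0
    return mean, sd_frac * mean


def p_rate_anchor(c_target: float, d0: float, gland_mass: float,
                  calcitriol: float, params_pop: PTGParameters) -> float:
    """Production scale making steady-state iPTH at the set-points equal
    ``c_target``.

    At the calcium set-point the activation is exactly 1/2 and the
    phosphate modifier is 1, so the closed-form steady state inverts to a
    production rate in pg/min per unit gland mass.
    """
    if c_target <= 0:
        raise DomainError("anchor iPTH must be > 0")
    p = params_pop
    f0 = p.k_act / (p.k_act + p.k_deact)          # active fraction at phi=1/2
    m_d = 1.0 - p.eps_d * calcitriol
    denom = 0.5 * d0 + 0.5 * p.sigma_max * f0
    secretion = 0.5 * p.sigma_max * f0
    return c_target * p.v_d * p.k_cl * denom / (secretion * gland_mass * m_d)


def build_params(free: np.ndarray, dataset: FitDataset, config
                 ) -> PTGParameters:
    """Materialize a full parameter set from the free vector."""
    k_set, p_opt, g0, d0, offset = free
    pop = PTGParameters.from_config(config)
    anchor = p_rate_anchor(dataset.anchor_ipth, d0, g0,
                           float(dataset.calcitriol), pop)
    return pop.replace(k_ca_setpoint=float(k_set), p_opt=float(p_opt),
                       gland_size0=float(g0), d0=float(d0),
                       p_rate=float(offset * anchor))


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _predict_window(params: PTGParameters, dataset: FitDataset
                    ) -> pd.DataFrame:
    state0 = PTGState(q=params.gland_size0 / 2, a=params.gland_size0 / 2,
                      s=1.0, c=1.0, t=float(dataset.days[0]), t_unit="day")
    return advance_slow(state0, dataset.daily_inputs(), params)


def _prior_residuals(free: np.ndarray, config,
                     gland_prior: tuple[float, float]) -> np.ndarray:
    """Standardized prior deviations (MAP shrinkage terms).

    A sparse monthly window (~6 draws) cannot identify the full parameter
    set from likelihood alone, so the fit shrinks toward population-scale
    priors: the calcium set-point is tightly regulated across patients,
    degradation and the production-anchor offset get weak lognormal
    priors, and gland mass follows the vintage prior.
    """
    est = config.estimation
    ref = config.individual_reference
    pr = est["priors"]
    k_set, p_opt, g0, d0, offset = free
    return np.array([
        (g0 - gland_prior[0]) / gland_prior[1],
        (k_set - ref["k_ca_setpoint"]) / pr["k_ca_setpoint_sd"],
        (p_opt - ref["p_opt"]) / pr["p_opt_sd"],
        np.log(d0 / ref["d0"]) / pr["d0_log_sd"],
        np.log(offset) / pr["p_rate_offset_log_sd"],
    ])


def residuals(free: np.ndarray, dataset: FitDataset, config,
              prior: tuple[float, float],
              prior_weight: float = 0.1) -> np.ndarray:
    """Log-scale iPTH residuals plus weighted prior penalties.

    iPTH spans more than an order of magnitude across patients and its
    errors are plausibly multiplicative, hence the log scale. The prior
    terms carry the observation-noise scale (MAP weighting): with data
    residuals left unweighted, a prior deviation of one sd must cost as
    much as a data residual of one noise sd. Any model evaluation failure
    returns an optimizer-safe large residual vector.
    """
    n = dataset.n_obs + 5
    try:
        params = build_params(free, dataset, config)
        traj = _predict_window(params, dataset)
        idx = (dataset.obs_days - dataset.days[0]).astype(int)
        c_pred = traj["c"].to_numpy()[idx]
        if np.any(~np.isfinite(c_pred)) or np.any(c_pred <= 0):
            return np.full(n, _FAILURE_RESIDUAL)
        r = np.log(c_pred) - np.log(dataset.obs_ipth)
        return np.concatenate(
            [r, prior_weight * _prior_residuals(free, config, prior)])
    except Exception:
        return np.full(n, _FAILURE_RESIDUAL)


def objective(free: np.ndarray, dataset: FitDataset, config,
              prior: Optional[tuple[float, float]] = None) -> float:
    """Scalar loss: sum of squared residuals (including the prior term)."""
    if prior is None:
        est = config.estimation
        prior = vintage_prior(dataset.vintage_days, est["vintage_gamma"],
                              est["vintage_sd_frac"])
    r = residuals(np.asarray(free, dtype=float), dataset, config, prior,
                  prior_weight=config.estimation["obs_log_sd"])
    return float(np.sum(r ** 2))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_bounds(config) -> tuple[np.ndarray, np.ndarray]:
    est = config.estimation
    b = est["bounds"]
    d0_ref = config.individual_reference["d0"]
    lo = np.array([b["k_ca_setpoint"][0], b["p_opt"][0],
                   b["gland_size0"][0], b["d0_frac"][0] * d0_ref,
                   b["p_rate_offset"][0]])
    hi = np.array([b["k_ca_setpoint"][1], b["p_opt"][1],
                   b["gland_size0"][1], b["d0_frac"][1] * d0_ref,
                   b["p_rate_offset"][1]])
    return lo, hi


def fit_patient(record: PatientRecord, config) -> FitResult:
    """Estimate the individualized parameter set for one patient.

    Bounded multi-start (Latin hypercube) trust-region least squares on
    log-iPTH residuals with a vintage-informed gland-mass prior.
    Deterministic given the configuration seed.

    Raises
    ------
    NotIndividualizableError
        For calcimimetic-exposed patients (the model carries no
        calcimimetic pharmacodynamics).
    InsufficientDataError
        If the window holds fewer observations than the configured minima.
    NonConvergenceError
        If no optimizer start converges.
    """
    if record.calcimimetic:
        raise NotIndividualizableError(
            f"{record.patient_id}: calcimimetic exposure — the model cannot "
            "be individualized to these patients")
    est = config.estimation
    dataset = assemble_window(record, est["window_days"])
    counts = {"ipth": dataset.n_obs, "ica": len(dataset.ca_obs),
              "phos": len(dataset.phos_obs)}
    minima = {"ipth": est["min_ipth_obs"], "ica": est["min_ica_obs"],
              "phos": est["min_phos_obs"]}
    for analyte, minimum in minima.items():
        if counts[analyte] < minimum:
            raise InsufficientDataError(
                f"{record.patient_id}: {counts[analyte]} {analyte} "
                f"observation(s) in window, need >= {minimum}")

    prior = vintage_prior(dataset.vintage_days, est["vintage_gamma"],
                          est["vintage_sd_frac"])
    lo, hi = _fit_bounds(config)
    ref = config.individual_reference
    reference = np.array([ref["k_ca_setpoint"], ref["p_opt"],
                          np.clip(prior[0], lo[2], hi[2]), ref["d0"], 1.0])

    sampler = qmc.LatinHypercube(d=len(FREE_PARAM_NAMES), seed=est["seed"])
    starts = qmc.scale(sampler.random(est["n_starts"]), lo, hi)

    # stage 1: multi-start MAP at the nominal observation-noise weight
    w0 = est["obs_log_sd"]
    best = None
    trace = []
    for i, x0 in enumerate(starts):
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            max_nfev=est["max_nfev"],
                            args=(dataset, config, prior),
                            kwargs={"prior_weight": w0})
        cost = float(np.sum(sol.fun ** 2))
        trace.append({"start": i, "cost": cost, "status": int(sol.status),
                      "nfev": int(sol.nfev)})
        if sol.status <= 0:
            continue
        dist = float(np.linalg.norm((sol.x - reference) / (hi - lo)))
        key = (cost, dist)
        if best is None or _better(key, best[0]):
            best = (key, sol)
    if best is None:
        raise NonConvergenceError(
            f"{record.patient_id}: no optimizer start converged")

    # stage 2: re-estimate the noise scale from the data residuals and
    # refit with the matching prior weight (empirical-Bayes reweighting;
    # noise-free data then carry effectively unregularized information)
    data_res = best[1].fun[:dataset.n_obs]
    sigma_hat = float(max(np.sqrt(np.mean(data_res ** 2)),
                          est["obs_log_sd_floor"]))
    sol = least_squares(residuals, best[1].x, bounds=(lo, hi), method="trf",
                        max_nfev=est["max_nfev"],
                        args=(dataset, config, prior),
                        kwargs={"prior_weight": sigma_hat})
    params = build_params(sol.x, dataset, config)
    traj = _predict_window(params, dataset)

    identifiable = {
        "k_ca_setpoint": bool(np.std(dataset.ca_obs) >=
                              est["ica_identifiability_sd"]),
        "p_opt": bool(len(dataset.phos_obs) > 0 and
                      np.std(dataset.phos_obs) >=
                      est["phos_identifiability_sd"]),
        "gland_size0": "prior_determined",
        "d0": True,
        "p_rate": "anchored_offset",
        "k_cl": "fixed_population",
    }
    free_named = dict(zip(FREE_PARAM_NAMES, (float(v) for v in sol.x)))
    diagnostics = {
        "free_params": free_named,
        "starts": trace,
        "n_starts": len(starts),
        "best_cost": float(np.sum(sol.fun ** 2)),
        "prior_mean": prior[0],
        "prior_sd": prior[1],
        "obs_log_sd_hat": sigma_hat,
        "anchor_ipth": dataset.anchor_ipth,
        "converged": True,
    }
    return FitResult(params=params,
                     loss=float(np.sum(sol.fun ** 2)),
                     n_obs=dataset.n_obs,
                     identifiable=identifiable,
                     diagnostics=diagnostics,
                     gland_mass_at_assessment=float(
                         traj.attrs["gland_mass_next"]))


def _better(key: tuple[float, float], other: tuple[float, float],
            rtol: float = 1e-9) -> bool:
    """Loss comparison with tie-break by distance to the reference vector."""
    cost, dist = key
    cost_o, dist_o = other
    if abs(cost - cost_o) <= rtol * max(1.0, abs(cost_o)):
        return dist < dist_o
    return cost < cost_o
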