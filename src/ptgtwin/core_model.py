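"""Mechanistic two-cell-population model of the parathyroid gland.

The gland is represented by quiescent cells ``q`` (which proliferate and
undergo apoptosis on a timescale of days to months) and secretory-active
cells ``a``. Active cells secrete a stored intraglandular PTH pool ``s``
into plasma, where intact PTH circulates at concentration ``c`` and is
cleared within minutes. Low ionized calcium (sensed through a steep
sigmoid, the "set-point" curve of the calcium-sensing receptor) drives
activation, secretion, reduced intracellular degradation and, chronically,
gland growth; phosphate stimulates and calcitriol suppresses hormone
production.

Two integration contracts are exposed:

* :func:`integrate_fast` — minute-resolved dynamics of one dialysis
  session (gland mass frozen);
* :func:`advance_slow` — day-by-day quasi-steady-state stepping of the
  gland over weeks to months.

The three response functions (calcium sensing ``phi``, phosphate modifier
``psi``, calcitriol modifier ``m_d``) are pluggable through
:class:`ResponseFunctions` so alternative functional forms can be dropped
in without touching the state equations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (
    DegenerateStateError,
    DomainError,
    IntegrationError,
    UnitTagError,
)

MINUTES_PER_DAY = 1440.0

#: physiological domain of the environmental inputs
CA_DOMAIN = (0.5, 2.0)    # mmol/l
PHOS_DOMAIN = (0.2, 4.0)  # mmol/l

#: numerical floor for gland mass in the slow engine
GLAND_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PTGParameters:
    """Patient-specific parameters plus population constants.

    The first six fields form the individualized set estimated per patient;
    the remainder are population constants taken from configuration.

    Units
    -----
    k_ca_setpoint, p_opt : mmol/l
    gland_size0 : dimensionless (healthy reference gland = 1)
    d0, k_cl, sigma_max, k_act, k_deact : 1/min
    p_rate : pg/min per unit gland mass
    lambda_max, mu : 1/day
    v_d : ml
    """

    k_ca_setpoint: float
    p_opt: float
    gland_size0: float
    d0: float
    p_rate: float
    k_cl: float
    h: float = 7.0
    sigma_max: float = 0.5
    k_act: float = 0.05
    k_deact: float = 0.05
    lambda_max: float = 0.004
    mu: float = 0.002
    alpha_p: float = 1.0
    eps_d: float = 0.3
    v_d: float = 3500.0

    def __post_init__(self):
        positive = ("gland_size0", "d0", "p_rate", "k_cl", "sigma_max",
                    "k_act", "k_deact", "lambda_max", "mu", "v_d")
        for name in positive:
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        if not self.h >= 1:
            raise DomainError("h must be >= 1")
        if not 0 <= self.eps_d < 1:
            raise DomainError("eps_d must lie in [0, 1)")
        if not 0.8 <= self.k_ca_setpoint <= 1.6:
            raise DomainError("k_ca_setpoint must lie in [0.8, 1.6] mmol/l")
        if not 0.6 <= self.p_opt <= 3.0:
            raise DomainError("p_opt must lie in [0.6, 3.0] mmol/l")
        if not self.alpha_p >= 0:
            raise DomainError("alpha_p must be >= 0")

    @classmethod
    def from_config(cls, config, **overrides) -> "PTGParameters":
        """Build parameters from a :class:`~ptgtwin.config.RunConfig`.

        Individualized fields default to the configured reference values
        and can be overridden by keyword.
        """
        fields = dict(config.population)
        fields.update(config.individual_reference)
        fields.update(overrides)
        return cls(**fields)

    def replace(self, **changes) -> "PTGParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PTGState:
    """Gland state at one time point.

    ``t`` is tagged with an explicit unit (``"min"`` in the fast context,
    ``"day"`` in the slow context); mixing untagged times is an error by
    construction.
    """

    q: float    # quiescent cell mass, dimensionless
    a: float    # secretory-active cell mass, dimensionless
    s: float    # stored intraglandular PTH, pg
    c: float    # plasma iPTH, pg/ml
    t: float
    t_unit: str  # "min" | "day"

    def __post_init__(self):
        for name in ("q", "a", "s", "c"):
            if not getattr(self, name) >= 0:
                raise DomainError(f"state variable {name} must be >= 0")
        if not self.q + self.a > 0:
            raise DegenerateStateError("gland mass q + a must be > 0")
        if self.t_unit not in ("min", "day"):
            raise UnitTagError(f"unknown time unit tag {self.t_unit!r}")

    @property
    def gland_mass(self) -> float:
        return self.q + self.a


@dataclass(frozen=True)
class EnvironmentInputs:
    """Time-dependent environmental drivers of the gland.

    ``ca`` and ``phos`` map time (in the unit of the calling context) to
    mmol/l; ``calcitriol`` maps time to a {0, 1} therapy indicator.
    """

    ca: Callable[[float], float]
    phos: Callable[[float], float]
    calcitriol: Callable[[float], float]

    @classmethod
    def constant(cls, ca: float, phos: float,
                 calcitriol: float = 0.0) -> "EnvironmentInputs":
        return cls(ca=lambda t: ca, phos=lambda t: phos,
                   calcitriol=lambda t: calcitriol)


# ---------------------------------------------------------------------------
# response functions (pluggable, D-style hooks)
# ---------------------------------------------------------------------------

def _default_phi(ca, params: PTGParameters):
    return 1.0 / (1.0 + (np.asarray(ca, dtype=float) / params.k_ca_setpoint)
                  ** params.h)


def _default_psi(phos, params: PTGParameters):
    raw = 1.0 + params.alpha_p * (np.asarray(phos, dtype=float)
                                  - params.p_opt) / params.p_opt
    return np.clip(raw, 0.2, 3.0)


def _default_m_d(calcitriol, params: PTGParameters):
    return 1.0 - params.eps_d * np.asarray(calcitriol, dtype=float)


@dataclass(frozen=True)
class ResponseFunctions:
    """The three gland response functions.

    ``phi(ca, params)`` — secretion/activation sigmoid in (0, 1);
    ``psi(phos, params)`` — phosphate production modifier;
    ``m_d(calcitriol, params)`` — calcitriol production modifier.
    """

    phi: Callable = field(default=_default_phi)
    psi: Callable = field(default=_default_psi)
    m_d: Callable = field(default=_default_m_d)


DEFAULT_RESPONSES = ResponseFunctions()


def secretion_activation(ca, params: PTGParameters,
                         responses: ResponseFunctions = DEFAULT_RESPONSES):
    """Calcium-sensing activation ``phi(ca) = 1 / (1 + (ca/set-point)^h)``.

    Strictly decreasing in calcium and exactly 1/2 at the patient's
    set-point. Accepts scalars or arrays.

    Raises
    ------
    DomainError
        If any calcium value is not strictly positive.
    """
    arr = np.asarray(ca, dtype=float)
    if np.any(~(arr > 0)):
        raise DomainError("ionized calcium must be strictly positive")
    out = responses.phi(arr, params)
    return float(out) if np.isscalar(ca) else out


# ---------------------------------------------------------------------------
# right-hand side and closed-form fixed point
# ---------------------------------------------------------------------------

def evaluate_rhs(state: PTGState, inputs_at_t, params: PTGParameters,
                 mode: str = "fast",
                 responses: ResponseFunctions = DEFAULT_RESPONSES):
    """Time derivatives ``(dq, da, ds, dc)`` of the gland state, per minute.

    ``inputs_at_t`` is a ``(ca, phos, calcitriol)`` triple. In ``"fast"``
    mode the proliferation/apoptosis term is dropped (gland mass is
    conserved over minutes); in ``"slow"`` mode it is included with the
    per-day rates converted to per-minute.
    """
    if mode not in ("fast", "slow"):
        raise ValueError(f"unknown mode {mode!r}")
    ca, phos, calcitriol = inputs_at_t
    g = state.q + state.a
    if not g > 0:
        raise DegenerateStateError("gland mass q + a must be > 0")
    phi = float(responses.phi(ca, params))
    psi = float(responses.psi(phos, params))
    m_d = float(responses.m_d(calcitriol, params))
    frac_active = state.a / g

    secretion = params.sigma_max * phi * frac_active * state.s
    ds = (params.p_rate * g * psi * m_d
          - params.d0 * (1.0 - phi) * state.s
          - secretion)
    dc = secretion / params.v_d - params.k_cl * state.c
    da = params.k_act * phi * state.q - params.k_deact * (1.0 - phi) * state.a
    dq = -params.k_act * phi * state.q + params.k_deact * (1.0 - phi) * state.a
    if mode == "slow":
        dq += (params.lambda_max * phi - params.mu) / MINUTES_PER_DAY * state.q
    return dq, da, ds, dc


def _fixed_point_arrays(phi, psi, m_d, gland_mass, params: PTGParameters):
    """Vectorized fast-subsystem fixed point at frozen gland mass.

    Returns arrays ``(q, a, s, c)`` for array-valued responses. Handles the
    ``phi == 0`` limit (no activation: everything quiescent, stored pool
    set by production/degradation balance, no circulating hormone).
    """
    phi = np.asarray(phi, dtype=float)
    g = np.asarray(gland_mass, dtype=float)
    act = params.k_act * phi
    deact = params.k_deact * (1.0 - phi)
    frac = np.where(act + deact > 0, act / np.where(act + deact > 0,
                                                    act + deact, 1.0), 0.0)
    a = g * frac
    q = g - a
    production = params.p_rate * g * psi * m_d
    denom = params.d0 * (1.0 - phi) + params.sigma_max * phi * frac
    s = production / np.where(denom > 0, denom, params.d0)
    c = params.sigma_max * phi * frac * s / (params.v_d * params.k_cl)
    return q, a, s, c


def steady_state(ca: float, phos: float, calcitriol: float,
                 gland_mass: float, params: PTGParameters,
                 responses: ResponseFunctions = DEFAULT_RESPONSES) -> PTGState:
    """Closed-form fast-subsystem fixed point at frozen gland mass.

    The active fraction balances activation against deactivation, the
    stored pool balances production against degradation plus secretion,
    and plasma iPTH balances secretion against clearance.
    """
    if not gland_mass > 0:
        raise DegenerateStateError("gland_mass must be > 0")
    lo, hi = CA_DOMAIN
    if not lo < ca < hi:
        raise DomainError(f"ca={ca} outside domain {CA_DOMAIN}")
    lo, hi = PHOS_DOMAIN
    if not lo < phos < hi:
        raise DomainError(f"phos={phos} outside domain {PHOS_DOMAIN}")
    phi = float(responses.phi(ca, params))
    psi = float(responses.psi(phos, params))
    m_d = float(responses.m_d(calcitriol, params))
    q, a, s, c = _fixed_point_arrays(phi, psi, m_d, gland_mass, params)
    return PTGState(q=float(q), a=float(a), s=float(s), c=float(c),
                    t=0.0, t_unit="min")


# ---------------------------------------------------------------------------
# fast integration (minutes)
# ---------------------------------------------------------------------------

def integrate_fast(state0: PTGState, inputs: EnvironmentInputs,
                   params: PTGParameters, duration: float,
                   rtol: float = 1e-6, atol: float = 1e-9,
                   responses: ResponseFunctions = DEFAULT_RESPONSES
                   ) -> pd.DataFrame:
    """Adaptive integration of the fast subsystem over ``duration`` minutes.

    Returns a frame with columns ``t_min, q, a, s, c`` sampled at 1-minute
    resolution (the final time is always included). The trajectory starts
    exactly at ``state0``.
    """
    if state0.t_unit != "min":
        raise UnitTagError("integrate_fast requires a minute-tagged state")
    if duration < 0:
        raise DomainError("duration must be >= 0")
    if duration == 0:
        return pd.DataFrame({"t_min": [state0.t], "q": [state0.q],
                             "a": [state0.a], "s": [state0.s],
                             "c": [state0.c]})

    t_eval = np.unique(np.concatenate([np.arange(0.0, duration, 1.0),
                                       [float(duration)]]))
    # validate the input signals on the sampling grid before integrating
    ca_grid = np.asarray([inputs.ca(t) for t in t_eval], dtype=float)
    phos_grid = np.asarray([inputs.phos(t) for t in t_eval], dtype=float)
    if np.any(ca_grid <= CA_DOMAIN[0]) or np.any(ca_grid >= CA_DOMAIN[1]):
        raise DomainError("ca(t) outside (0.5, 2.0) mmol/l on [0, duration]")
    if np.any(phos_grid <= PHOS_DOMAIN[0]) or np.any(phos_grid >= PHOS_DOMAIN[1]):
        raise DomainError("phos(t) outside (0.2, 4.0) mmol/l on [0, duration]")

    def rhs(t, y):
        st = _RawState(*y)
        return evaluate_rhs(st, (inputs.ca(t), inputs.phos(t),
                                 inputs.calcitriol(t)),
                            params, mode="fast", responses=responses)

    y0 = [state0.q, state0.a, state0.s, state0.c]
    sol = solve_ivp(rhs, (0.0, float(duration)), y0, method="RK45",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"fast integration failed: {sol.message}")
    y = sol.y
    if np.min(y) < -1e-6:
        raise IntegrationError("integration produced significantly negative "
                               f"state (min={np.min(y):.3e})")
    y = np.maximum(y, 0.0)
    return pd.DataFrame({"t_min": sol.t + state0.t, "q": y[0], "a": y[1],
                         "s": y[2], "c": y[3]})


class _RawState:
    """Duck-typed state for RHS evaluation inside the solver loop.

    Skips the dataclass validation so transient tiny negatives produced by
    the adaptive stepper do not abort the solve; invariants are enforced on
    the returned trajectory instead.
    """

    __slots__ = ("q", "a", "s", "c")

    def __init__(self, q, a, s, c):
        self.q = q
        self.a = a
        self.s = s
        self.c = c


# ---------------------------------------------------------------------------
# slow engine (days): quasi-steady-state stepping
# ---------------------------------------------------------------------------

def advance_slow(state0: PTGState, daily_inputs, params: PTGParameters,
                 responses: ResponseFunctions = DEFAULT_RESPONSES
                 ) -> pd.DataFrame:
    """Advance the gland day by day under piecewise-constant daily inputs.

    For each day the fast subsystem is assumed equilibrated at that day's
    inputs and the current gland mass (quasi-steady state); gland mass is
    then advanced by one day of the proliferation/apoptosis dynamics acting
    on the quiescent pool:

        dg/dt = (lambda_max * phi - mu) * (1 - f_active) * g

    integrated exactly over the day (exponential update). Equal transition
    rates make the active fraction ``f_active = phi``.

    Parameters
    ----------
    state0 : PTGState
        Day-tagged state; only the gland mass (and the day stamp) is used.
    daily_inputs : sequence of (ca, phos, calcitriol)
        One triple per day, first entry applying to ``state0.t``.

    Returns
    -------
    pandas.DataFrame
        One row per day with columns ``day, q, a, s, c, gland_mass``
        (``c`` is the quasi-steady plasma iPTH at that day's inputs and the
        gland mass *before* the day's growth step). The frame's
        ``attrs["gland_floor_hit"]`` flags a collapse clamped at 1e-6.
    """
    if state0.t_unit != "day":
        raise UnitTagError("advance_slow requires a day-tagged state")
    arr = np.asarray(daily_inputs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
        raise DomainError("daily_inputs must be a non-empty sequence of "
                          "(ca, phos, calcitriol) triples")
    ca, phos, cal = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(ca <= CA_DOMAIN[0]) or np.any(ca >= CA_DOMAIN[1]):
        raise DomainError("daily ca outside (0.5, 2.0) mmol/l")
    if np.any(phos <= PHOS_DOMAIN[0]) or np.any(phos >= PHOS_DOMAIN[1]):
        raise DomainError("daily phos outside (0.2, 4.0) mmol/l")

    phi = np.asarray(responses.phi(ca, params), dtype=float)
    psi = np.asarray(responses.psi(phos, params), dtype=float)
    m_d = np.asarray(responses.m_d(cal, params), dtype=float)
    act = params.k_act * phi
    deact = params.k_deact * (1.0 - phi)
    frac = act / (act + deact)
    # per-day relative growth of total gland mass
    growth = (params.lambda_max * phi - params.mu) * (1.0 - frac)

    g0 = state0.gland_mass
    log_g = np.log(g0) + np.concatenate([[0.0], np.cumsum(growth[:-1])])
    floor_hit = bool(np.any(log_g < np.log(GLAND_FLOOR)))
    g = np.exp(np.maximum(log_g, np.log(GLAND_FLOOR)))

    q, a, s, c = _fixed_point_arrays(phi, psi, m_d, g, params)
    days = state0.t + np.arange(arr.shape[0], dtype=float)
    out = pd.DataFrame({"day": days, "q": q, "a": a, "s": s, "c": c,
                        "gland_mass": g})
    out.attrs["gland_floor_hit"] = floor_hit
    # gland mass entering the day after the last input (for chaining)
    out.attrs["gland_mass_next"] = float(
        max(np.exp(max(log_g[-1] + growth[-1], np.log(GLAND_FLOOR))),
            GLAND_FLOOR))
    return out
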