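"""Virtual hemodialysis cohorts with known ground-truth gland physiology.

The study cohort this generator emulates is a small maintenance-HD
population under routine monthly labs: dialysis vintage lognormal around a
median of ~218 days, pre-dialysis ionized calcium around 1.17 mmol/l,
6-month phosphate around 1.78 mmol/l, 6-month average iPTH in the few
hundreds of pg/ml, and a single 240-minute study dialysis session against
a high-calcium dialysate that raises blood iCa by ~0.2 mmol/l.

Every patient carries true gland parameters, latent daily iCa/phosphate
paths (bounded random walks, so real 6-month trends exist for the slow
engine to exploit), model-true daily iPTH, and noisy observed labs on a
jittered monthly schedule. A ground-truth sidecar retains everything the
pipeline is never allowed to see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import PTGParameters, PTGState, advance_slow
from .errors import DomainError
from .personalization import PatientRecord, p_rate_anchor
from .prediction import DialysisSession, simulate_session
from .validation_stats import DROPOUT_EVENTS

#: fixed synthetic calendar anchor for the cohort's assessment day
ASSESSMENT_DATE = Date(2021, 6, 15)

#: latent-path bounds (reflecting random walks stay inside)
CA_WALK_BOUNDS = (1.00, 1.40)
PHOS_WALK_BOUNDS = (0.80, 2.60)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one virtual cohort."""

    n_patients: int = 26
    seed: int = 0
    lab_interval_days: int = 30
    lab_jitter_days: int = 5
    session_duration_min: float = 240.0
    ipth_cv: float = 0.10          # multiplicative lognormal noise on iPTH
    ica_sd: float = 0.02           # additive noise on iCa, mmol/l
    phos_cv: float = 0.08          # multiplicative noise on phosphate
    horizon_days: int = 180
    # intradialytic iCa profile: exponential approach toward the
    # dialysate-side ionized level
    ca_dialysate_mean: float = 1.50
    ca_dialysate_sd: float = 0.05
    tau_range: tuple = (240.0, 420.0)   # approach time constant, min
    # per-parameter dispersion of the true physiology
    setpoint_mean: float = 1.15
    setpoint_sd: float = 0.05
    setpoint_bounds: tuple = (1.0, 1.3)
    p_opt_mean: float = 1.5
    p_opt_sd: float = 0.15
    d0_log_sd: float = 0.2
    gland_log_sd: float = 0.15
    baseline_ipth_median: float = 326.0
    baseline_ipth_log_sd: float = 0.5
    vintage_median_days: float = 218.0
    vintage_log_sd: float = 1.0
    # daily random-walk steps of the latent electrolyte paths
    ca_walk_step: float = 0.004
    phos_walk_step: float = 0.010

    def __post_init__(self):
        if self.n_patients < 1:
            raise DomainError("n_patients must be >= 1")
        if self.lab_interval_days < 1:
            raise DomainError("lab_interval_days must be >= 1")
        for name in ("ipth_cv", "ica_sd", "phos_cv"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass
class TruePatient:
    """Ground-truth physiology of one virtual patient."""

    patient_id: str
    params: PTGParameters
    vintage_days: float
    calcitriol: int
    baseline_ipth: float


@dataclass
class PatientTruth:
    """Per-patient ground-truth sidecar (never read by the pipeline)."""

    params: PTGParameters
    daily: pd.DataFrame          # day, ca, phos, ipth_true, gland_mass
    session_pre: float
    session_post: float


@dataclass
class CohortBundle:
    """A complete synthetic study: observables plus ground truth."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    sessions: pd.DataFrame
    truth: dict = field(default_factory=dict)
    spec: SyntheticCohortSpec = None

    def records(self) -> list:
        """Observable patient records (for the fitting pipeline)."""
        out = []
        for row in self.patients.itertuples():
            labs = self.labs[self.labs["patient_id"] == row.patient_id]
            out.append(PatientRecord(
                patient_id=row.patient_id,
                vintage_days=float(row.vintage_days),
                calcitriol=int(row.calcitriol),
                calcimimetic=int(row.calcimimetic),
                assessment_date=pd.Timestamp(row.assessment_date).date(),
                labs=labs[["date", "analyte", "value", "unit"]].copy()))
        return out

    def session_objects(self) -> dict:
        out = {}
        for pid, grp in self.sessions.groupby("patient_id"):
            grp = grp.sort_values("t_min")
            first = grp.iloc[0]
            out[pid] = DialysisSession(
                patient_id=pid,
                session_date=pd.Timestamp(first["session_date"]).date(),
                ica_points=tuple(zip(grp["t_min"], grp["ica_mmol_l"])),
                duration_min=float(grp["t_min"].max()),
                ipth_pre=float(first["ipth_pre"]),
                ipth_post=float(first["ipth_post"]))
        return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sample_cohort_params(spec: SyntheticCohortSpec, config,
                         rng: np.random.Generator | None = None
                         ) -> list[TruePatient]:
    """Draw true gland parameters, vintage and therapy flags per patient.

    The production scale of each patient is set through the anchor
    identity so that their steady-state iPTH at their own set-points
    equals a drawn baseline iPTH (lognormal around the cohort median);
    this keeps the virtual cohort's hormone levels on the clinically
    observed scale by construction.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pop = PTGParameters.from_config(config)
    d0_ref = config.individual_reference["d0"]
    patients = []
    for i in range(spec.n_patients):
        pid = f"p{i + 1:03d}"
        a = (spec.setpoint_bounds[0] - spec.setpoint_mean) / spec.setpoint_sd
        b = (spec.setpoint_bounds[1] - spec.setpoint_mean) / spec.setpoint_sd
        k_set = float(stats.truncnorm.rvs(a, b, loc=spec.setpoint_mean,
                                          scale=spec.setpoint_sd,
                                          random_state=rng))
        p_opt = float(np.clip(rng.normal(spec.p_opt_mean, spec.p_opt_sd),
                              1.0, 2.2))
        vintage = float(spec.vintage_median_days *
                        np.exp(rng.normal(0.0, spec.vintage_log_sd)))
        calcitriol = int(rng.random() < 0.5)
        gland = float((1.0 + 0.3 * vintage / 365.0) *
                      np.exp(rng.normal(0.0, spec.gland_log_sd)))
        gland = float(np.clip(gland, 0.3, 6.0))
        d0 = float(d0_ref * np.exp(rng.normal(0.0, spec.d0_log_sd)))
        c_base = float(np.clip(
            spec.baseline_ipth_median *
            np.exp(rng.normal(0.0, spec.baseline_ipth_log_sd)), 50.0, 900.0))
        p_rate = p_rate_anchor(c_base, d0, gland, float(calcitriol), pop)
        params = pop.replace(k_ca_setpoint=k_set, p_opt=p_opt,
                             gland_size0=gland, d0=d0, p_rate=p_rate)
        patients.append(TruePatient(patient_id=pid, params=params,
                                    vintage_days=vintage,
                                    calcitriol=calcitriol,
                                    baseline_ipth=c_base))
    return patients


def _reflecting_walk(rng, n: int, start: float, step_sd: float,
                     bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    x = np.empty(n)
    x[0] = np.clip(start, lo, hi)
    steps = rng.normal(0.0, step_sd, size=n - 1)
    for i in range(1, n):
        v = x[i - 1] + steps[i - 1]
        if v < lo:
            v = lo + (lo - v)
        if v > hi:
            v = hi - (v - hi)
        x[i] = np.clip(v, lo, hi)
    return x


def generate_longitudinal_labs(tp: TruePatient, spec: SyntheticCohortSpec,
                               rng: np.random.Generator
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent daily paths, model-true iPTH and noisy observed labs.

    Returns ``(labs, daily_truth)`` where ``labs`` has the observable
    schema (date, analyte, value, unit) over days −180..+180 relative to
    the assessment and ``daily_truth`` holds the latent paths, true daily
    iPTH and gland mass.
    """
    horizon = spec.horizon_days
    days = np.arange(-horizon, horizon + 1)
    n = len(days)
    ca0 = float(np.clip(rng.normal(1.17, 0.05), *CA_WALK_BOUNDS))
    phos0 = float(np.clip(rng.normal(1.78, 0.25), *PHOS_WALK_BOUNDS))
    ca_lat = _reflecting_walk(rng, n, ca0, spec.ca_walk_step, CA_WALK_BOUNDS)
    phos_lat = _reflecting_walk(rng, n, phos0, spec.phos_walk_step,
                                PHOS_WALK_BOUNDS)
    cal = np.full(n, float(tp.calcitriol))

    g0 = tp.params.gland_size0
    state0 = PTGState(q=g0 / 2, a=g0 / 2, s=1.0, c=1.0,
                      t=float(days[0]), t_unit="day")
    traj = advance_slow(state0, np.column_stack([ca_lat, phos_lat, cal]),
                        tp.params)
    daily_truth = pd.DataFrame({
        "day": days, "ca": ca_lat, "phos": phos_lat,
        "ipth_true": traj["c"].to_numpy(),
        "gland_mass": traj["gland_mass"].to_numpy()})

    nominal = np.arange(-horizon, horizon + 1, spec.lab_interval_days)
    jitter = rng.integers(-spec.lab_jitter_days, spec.lab_jitter_days + 1,
                          size=len(nominal)) if spec.lab_jitter_days else \
        np.zeros(len(nominal), dtype=int)
    draw_days = np.unique(np.clip(nominal + jitter, -horizon, horizon))

    day_index = {int(d): i for i, d in enumerate(days)}
    rows = []
    for d in draw_days:
        i = day_index[int(d)]
        date = ASSESSMENT_DATE + timedelta(days=int(d))
        ica_obs = float(np.clip(ca_lat[i] + rng.normal(0.0, spec.ica_sd),
                                0.8, 1.8))
        phos_obs = float(np.clip(
            phos_lat[i] * np.exp(rng.normal(0.0, spec.phos_cv)), 0.3, 3.9))
        ipth_obs = float(daily_truth["ipth_true"].iloc[i] *
                         np.exp(rng.normal(0.0, spec.ipth_cv)))
        rows += [
            {"patient_id": tp.patient_id, "date": date, "analyte": "ica",
             "value": round(ica_obs, 4), "unit": "mmol/l"},
            {"patient_id": tp.patient_id, "date": date, "analyte": "phos",
             "value": round(phos_obs, 4), "unit": "mmol/l"},
            {"patient_id": tp.patient_id, "date": date, "analyte": "ipth",
             "value": round(ipth_obs, 2), "unit": "pg/ml"},
        ]
    return pd.DataFrame(rows), daily_truth


def generate_session(tp: TruePatient, spec: SyntheticCohortSpec,
                     rng: np.random.Generator,
                     phos_at_session: float = 1.78,
                     ca_ambient: float | None = None,
                     gland_mass: float | None = None
                     ) -> tuple[DialysisSession, float, float]:
    """One study dialysis session against a high-calcium dialysate.

    Blood iCa approaches the dialysate-side ionized level exponentially,
    ``ca(t) = ca_d − (ca_d − ca_0)·exp(−t/τ)``; draws every 60 minutes.
    True pre/post iPTH come from the fast model at the true parameters,
    initialized at the steady state for the session-start iCa and, when
    given, the patient's true gland mass on the session day.

    The pre-dialysis iCa samples the patient's own ambient calcium that
    morning (``ca_ambient`` plus a small peridialytic offset); without an
    ambient value it falls back to the cohort-level distribution.
    """
    if ca_ambient is None:
        ca0 = float(stats.truncnorm.rvs((1.01 - 1.17) / 0.06,
                                        (1.31 - 1.17) / 0.06,
                                        loc=1.17, scale=0.06,
                                        random_state=rng))
    else:
        ca0 = float(np.clip(ca_ambient + rng.normal(0.0, 0.02), 1.01, 1.31))
    # positive dialysate-to-blood gradient by construction
    ca_d = float(np.clip(rng.normal(spec.ca_dialysate_mean,
                                    spec.ca_dialysate_sd),
                         max(1.36, ca0 + 0.05), 1.70))
    tau = float(rng.uniform(*spec.tau_range))
    times = np.arange(0.0, spec.session_duration_min + 1.0, 60.0)
    values = ca_d - (ca_d - ca0) * np.exp(-times / tau)
    session = DialysisSession(
        patient_id=tp.patient_id, session_date=ASSESSMENT_DATE,
        ica_points=tuple(zip(times, np.round(values, 4))),
        duration_min=float(times[-1]))
    initial = None
    if gland_mass is not None:
        from .core_model import steady_state
        initial = steady_state(session.values[0], phos_at_session,
                               float(tp.calcitriol), gland_mass, tp.params)
    pred = simulate_session(tp.params, session, initial=initial,
                            phos=phos_at_session,
                            calcitriol=float(tp.calcitriol))
    session = DialysisSession(
        patient_id=session.patient_id, session_date=session.session_date,
        ica_points=session.ica_points, duration_min=session.duration_min,
        ipth_pre=round(pred.pre, 3), ipth_post=round(pred.post, 3))
    return session, pred.pre, pred.post


def generate_cohort(spec: SyntheticCohortSpec, config,
                    out_dir=None) -> CohortBundle:
    """Compose the full synthetic study bundle, deterministically.

    A single seeded generator is consumed in a fixed order (parameters,
    then per-patient labs and session), so identical specs yield
    byte-identical bundles. If ``out_dir`` is given the bundle is written
    through the interfaces module.
    """
    rng = np.random.default_rng(spec.seed)
    cohort = sample_cohort_params(spec, config, rng)

    patient_rows, lab_frames, session_rows, truth = [], [], [], {}
    for tp in cohort:
        labs, daily_truth = generate_longitudinal_labs(tp, spec, rng)
        at_index = daily_truth[daily_truth["day"] == 0].iloc[0]
        session, pre, post = generate_session(
            tp, spec, rng, phos_at_session=float(at_index["phos"]),
            ca_ambient=float(at_index["ca"]),
            gland_mass=float(at_index["gland_mass"]))
        patient_rows.append({
            "patient_id": tp.patient_id,
            "vintage_days": round(tp.vintage_days, 1),
            "calcitriol": tp.calcitriol, "calcimimetic": 0,
            "assessment_date": ASSESSMENT_DATE})
        lab_frames.append(labs)
        for j, (t, v) in enumerate(session.ica_points):
            session_rows.append({
                "patient_id": tp.patient_id,
                "session_date": ASSESSMENT_DATE, "t_min": t,
                "ica_mmol_l": v,
                "ipth_pre": session.ipth_pre if j == 0 else "",
                "ipth_post": session.ipth_post if j == 0 else ""})
        truth[tp.patient_id] = PatientTruth(
            params=tp.params, daily=daily_truth,
            session_pre=pre, session_post=post)

    bundle = CohortBundle(patients=pd.DataFrame(patient_rows),
                          labs=pd.concat(lab_frames, ignore_index=True),
                          sessions=pd.DataFrame(session_rows),
                          truth=truth, spec=spec)
    if out_dir is not None:
        from .interfaces import write_bundle
        write_bundle(bundle, out_dir)
    return bundle


def inject_dropout_events(patient_ids, n_events: int, seed: int,
                          assessment_date: Date = ASSESSMENT_DATE
                          ) -> pd.DataFrame:
    """Post-index dropout events exercising the long-term eligibility rules.

    Picks ``n_events`` distinct patients and assigns each one qualifying
    event (transplant, calcimimetic start, transfer or death) at a random
    day within 180 days after the assessment.
    """
    ids = list(patient_ids)
    if n_events > len(ids):
        raise DomainError("cannot inject more events than patients")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(ids, size=n_events, replace=False)
    rows = []
    for pid in chosen:
        event = DROPOUT_EVENTS[int(rng.integers(0, len(DROPOUT_EVENTS)))]
        day = int(rng.integers(1, 181))
        rows.append({"patient_id": pid, "event": event,
                     "date": assessment_date + timedelta(days=day)})
    return pd.DataFrame(rows, columns=["patient_id", "event", "date"])
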