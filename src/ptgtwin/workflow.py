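"""End-to-end study workflows over a cohort bundle.

These functions reproduce the validation design of the clinical study on
any bundle (synthetic or real): individualize each eligible patient on the
pre-assessment window, predict the peridialytic iPTH change of the study
session from measured intradialytic calcium, and predict the 6-month iPTH
with the weekly-median readout at the reference measurement.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import steady_state
from .errors import InsufficientDataError, NotIndividualizableError
from .personalization import FitResult, PatientRecord, fit_patient
from .prediction import (
    DialysisSession,
    ScenarioSpec,
    predict_longterm,
    simulate_session,
    weekly_median,
)


def _rel_days(record: PatientRecord) -> pd.DataFrame:
    labs = record.labs.copy()
    labs["day"] = [(d - record.assessment_date).days for d in labs["date"]]
    return labs


def _latest_pre_index(labs: pd.DataFrame, analyte: str):
    rows = labs[(labs["analyte"] == analyte) & (labs["day"] <= 0)]
    if rows.empty:
        return None
    return float(rows.sort_values("day")["value"].iloc[-1])


def fit_cohort(records, config) -> dict[str, FitResult]:
    """Individualize every fittable patient; skip the excluded ones."""
    fits: dict[str, FitResult] = {}
    for record in records:
        try:
            fits[record.patient_id] = fit_patient(record, config)
        except (NotIndividualizableError, InsufficientDataError):
            continue
    return fits


def predict_sessions(records, sessions: Mapping[str, DialysisSession],
                     fits: Mapping[str, FitResult]) -> pd.DataFrame:
    """Predicted peridialytic change per fitted patient with a session.

    The session starts from the fast steady state at the first measured
    intradialytic iCa, the latest pre-index phosphate on file, and the
    fitted gland mass at the assessment date.
    """
    rows = []
    by_id = {r.patient_id: r for r in records}
    for pid, fit in fits.items():
        session = sessions.get(pid)
        if session is None:
            continue
        record = by_id[pid]
        labs = _rel_days(record)
        phos = _latest_pre_index(labs, "phos") or fit.params.p_opt
        initial = steady_state(session.values[0], phos,
                               float(record.calcitriol),
                               fit.gland_mass_at_assessment, fit.params)
        pred = simulate_session(fit.params, session, initial=initial,
                                phos=phos,
                                calcitriol=float(record.calcitriol))
        rows.append({"patient_id": pid, "date": session.session_date,
                     "pre_pred": pred.pre, "post_pred": pred.post,
                     "delta": pred.delta, "delta_pct": pred.delta_pct,
                     "pre_meas": session.ipth_pre,
                     "post_meas": session.ipth_post})
    return pd.DataFrame(rows)


def longterm_weekly_predictions(records, fits: Mapping[str, FitResult],
                                include_ids=None,
                                horizon_days: int = 180) -> pd.DataFrame:
    """Weekly-median 6-month prediction against the reference iPTH.

    For each patient the engine is driven by the actual post-index labs
    (scenario ``none``); the prediction compared with the measurement is
    the median of predicted daily values in the week of the iPTH draw
    closest to the horizon.
    """
    rows = []
    for record in records:
        pid = record.patient_id
        if pid not in fits or (include_ids is not None
                               and pid not in include_ids):
            continue
        fit = fits[pid]
        labs = _rel_days(record)
        post = labs[labs["day"] > 0][["day", "analyte", "value"]]
        ipth_post = post[post["analyte"] == "ipth"]
        if ipth_post.empty:
            continue
        ref_idx = (ipth_post["day"] - horizon_days).abs().idxmin()
        ref_day = int(ipth_post.loc[ref_idx, "day"])
        ref_value = float(ipth_post.loc[ref_idx, "value"])
        baseline_ica = _latest_pre_index(labs, "ica")
        baseline_phos = _latest_pre_index(labs, "phos")
        if baseline_ica is None:
            continue
        try:
            series = predict_longterm(
                fit.params, post, ScenarioSpec("none", 0.0, horizon_days),
                baseline_ica=baseline_ica,
                baseline_phos=baseline_phos
                if baseline_phos is not None else 1.5,
                horizon_days=max(horizon_days, ref_day),
                calcitriol=float(record.calcitriol),
                gland_mass_start=fit.gland_mass_at_assessment)
            predicted = weekly_median(series, ref_day)
        except InsufficientDataError:
            continue
        rows.append({"patient_id": pid, "reference_day": ref_day,
                     "measured": ref_value, "predicted": predicted})
    return pd.DataFrame(rows)
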