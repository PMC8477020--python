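"""Agreement statistics and cohort eligibility filters.

Pearson and Kendall tau-b correlations (through scipy), Bland–Altman
limits of agreement with a proportional-bias test, and the two-stage
eligibility filter of the validation cohort: calcimimetic exposure before
the assessment excludes a patient from individualization outright, and any
calcimimetic start, kidney transplantation, facility transfer or death
within 180 days after the assessment removes them from the long-term
validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BundleValidationError,
    DomainError,
    InsufficientDataError,
    UndefinedStatisticError,
)

STAGES = ("individualization", "longterm_validation")

#: event types that disqualify a patient from long-term validation
DROPOUT_EVENTS = ("calcimimetic", "transplant", "transfer", "death")

LONGTERM_WINDOW_DAYS = 180


@dataclass(frozen=True)
class AgreementSummary:
    """Bland–Altman agreement between measured and predicted values.

    Differences are oriented measured − predicted; limits of agreement are
    mean ± 1.96 sample standard deviations. Proportional bias is the
    Pearson correlation of the differences against the pair means.
    """

    n: int
    pearson_r: float
    p_value: float
    mean_diff: float
    loa_lower: float
    loa_upper: float
    prop_bias_r: float
    prop_bias_p: float
    prop_bias_defined: bool = True


def _as_arrays(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("inputs must be equal-length 1-d sequences")
    if len(x) < min_n:
        raise InsufficientDataError(f"need >= {min_n} pairs, got {len(x)}")
    return x, y


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x, y = _as_arrays(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def kendall_taub(x, y) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) with the normal-approximation p-value."""
    x, y = _as_arrays(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "tau-b undefined when either vector is fully tied")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bland_altman(measured, predicted) -> AgreementSummary:
    """Bland–Altman agreement analysis of measured vs predicted values."""
    m, p = _as_arrays(measured, predicted)
    d = m - p
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_lower = mean_diff - 1.96 * sd
    loa_upper = mean_diff + 1.96 * sd
    pair_mean = (m + p) / 2.0
    try:
        r, pr = pearson_corr(d, pair_mean)
        defined = True
    except UndefinedStatisticError:
        # perfect (or constant-offset) agreement: no bias to correlate
        r, pr, defined = 0.0, float("nan"), False
    try:
        corr_r, corr_p = pearson_corr(m, p)
    except UndefinedStatisticError:
        corr_r, corr_p = float("nan"), float("nan")
    return AgreementSummary(n=len(m), pearson_r=corr_r, p_value=corr_p,
                            mean_diff=mean_diff, loa_lower=loa_lower,
                            loa_upper=loa_upper, prop_bias_r=r,
                            prop_bias_p=pr, prop_bias_defined=defined)


def eligibility_filter(patients: pd.DataFrame, events: pd.DataFrame,
                       stage: str) -> tuple[list, pd.DataFrame]:
    """Apply the cohort eligibility rules for one validation stage.

    Parameters
    ----------
    patients : DataFrame
        Columns ``patient_id, calcimimetic, assessment_date``.
    events : DataFrame
        Columns ``patient_id, event, date`` (may be empty). Event types
        are restricted to :data:`DROPOUT_EVENTS`.
    stage : {"individualization", "longterm_validation"}

    Returns
    -------
    (included_ids, exclusions)
        Sorted list of eligible patient ids and a DataFrame of
        ``patient_id, reason`` rows (one per exclusion reason).
    """
    if stage not in STAGES:
        raise DomainError(f"unknown stage {stage!r}; expected one of {STAGES}")
    required = {"patient_id", "calcimimetic", "assessment_date"}
    if not required.issubset(patients.columns):
        raise BundleValidationError(
            f"patients table needs columns {sorted(required)}")
    if len(events):
        if not {"patient_id", "event", "date"}.issubset(events.columns):
            raise BundleValidationError(
                "events table needs columns patient_id, event, date")
        if events["date"].isna().any():
            bad = events.index[events["date"].isna()].tolist()
            raise BundleValidationError("undated event", rows=bad)
        unknown = ~events["event"].isin(DROPOUT_EVENTS)
        if unknown.any():
            raise BundleValidationError(
                f"unknown event types: "
                f"{sorted(events.loc[unknown, 'event'].unique())}")

    assessment = {row.patient_id: pd.Timestamp(row.assessment_date)
                  for row in patients.itertuples()}
    exclusions: list[tuple] = []
    excluded: set = set()

    for row in patients.itertuples():
        if row.calcimimetic:
            excluded.add(row.patient_id)
            exclusions.append((row.patient_id,
                               "calcimimetic_before_assessment"))
    if len(events):
        ev = events.copy()
        ev["date"] = pd.to_datetime(ev["date"])
        for row in ev.itertuples():
            if row.patient_id not in assessment:
                continue
            offset = (row.date - assessment[row.patient_id]).days
            if row.event == "calcimimetic" and offset <= 0 \
                    and row.patient_id not in excluded:
                excluded.add(row.patient_id)
                exclusions.append((row.patient_id,
                                   "calcimimetic_before_assessment"))
            if stage == "longterm_validation" and \
                    0 < offset <= LONGTERM_WINDOW_DAYS and \
                    row.patient_id not in excluded:
                excluded.add(row.patient_id)
                exclusions.append((row.patient_id, f"{row.event}_within_180d"))

    included = sorted(pid for pid in patients["patient_id"]
                      if pid not in excluded)
    excl_df = pd.DataFrame(sorted(set(exclusions)),
                           columns=["patient_id", "reason"])
    return included, excl_df
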