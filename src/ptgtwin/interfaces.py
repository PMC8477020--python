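"""Tabular file formats tying the pipeline together.

All tables are plain UTF-8 CSV with ISO-8601 dates; patient parameter sets
serialize to flat ``key = value`` text files. Readers validate schema,
units and key uniqueness and report offending row numbers.

Files
-----
patients.csv : patient_id, vintage_days, calcitriol, calcimimetic, assessment_date
labs.csv : patient_id, date, analyte{ica|phos|ipth}, value, unit
sessions.csv : patient_id, session_date, t_min, ica_mmol_l [, ipth_pre, ipth_post]
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core_model import PTGParameters
from .errors import BundleValidationError
from .personalization import ANALYTE_UNITS, PatientRecord
from .prediction import DialysisSession

PATIENT_COLUMNS = ["patient_id", "vintage_days", "calcitriol",
                   "calcimimetic", "assessment_date"]
LAB_COLUMNS = ["patient_id", "date", "analyte", "value", "unit"]
SESSION_COLUMNS = ["patient_id", "session_date", "t_min", "ica_mmol_l"]


@dataclass
class BundleData:
    """Validated collections read from a bundle directory."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    sessions: pd.DataFrame

    def records(self) -> list[PatientRecord]:
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

    def session_objects(self) -> dict[str, DialysisSession]:
        out = {}
        for pid, grp in self.sessions.groupby("patient_id"):
            grp = grp.sort_values("t_min")
            first = grp.iloc[0]
            kwargs = {}
            for key in ("ipth_pre", "ipth_post"):
                if key in grp.columns and pd.notna(first[key]) \
                        and first[key] != "":
                    kwargs[key] = float(first[key])
            out[pid] = DialysisSession(
                patient_id=pid,
                session_date=pd.Timestamp(first["session_date"]).date(),
                ica_points=tuple(zip(grp["t_min"].astype(float),
                                     grp["ica_mmol_l"].astype(float))),
                duration_min=float(grp["t_min"].max()), **kwargs)
        return out


def _require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise BundleValidationError(f"{name}: missing column(s) {missing}")


def _parse_dates(df: pd.DataFrame, column: str, name: str) -> pd.DataFrame:
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        raise BundleValidationError(f"{name}: unparseable {column}",
                                    rows=df.index[bad].tolist())
    if df[column].isna().any():
        raise BundleValidationError(f"{name}: missing {column}",
                                    rows=df.index[df[column].isna()].tolist())
    out = df.copy()
    out[column] = parsed.dt.date
    return out


def read_bundle(path) -> BundleData:
    """Read and validate ``patients.csv``, ``labs.csv``, ``sessions.csv``.

    Raises
    ------
    BundleValidationError
        On missing columns, bad units, unparseable dates or duplicate
        (patient, date, analyte) rows — always naming the offending rows.
    """
    path = Path(path)
    patients = pd.read_csv(path / "patients.csv")
    labs = pd.read_csv(path / "labs.csv")
    sessions = pd.read_csv(path / "sessions.csv")

    _require_columns(patients, PATIENT_COLUMNS, "patients.csv")
    _require_columns(labs, LAB_COLUMNS, "labs.csv")
    _require_columns(sessions, SESSION_COLUMNS, "sessions.csv")

    patients = _parse_dates(patients, "assessment_date", "patients.csv")
    if patients["patient_id"].duplicated().any():
        dup = patients.index[patients["patient_id"].duplicated()].tolist()
        raise BundleValidationError("patients.csv: duplicate patient_id",
                                    rows=dup)

    if len(labs):
        labs = _parse_dates(labs, "date", "labs.csv")
        bad_analyte = ~labs["analyte"].isin(ANALYTE_UNITS)
        if bad_analyte.any():
            raise BundleValidationError(
                "labs.csv: unknown analyte",
                rows=labs.index[bad_analyte].tolist())
        expected = labs["analyte"].map(ANALYTE_UNITS)
        bad_unit = labs["unit"] != expected
        if bad_unit.any():
            raise BundleValidationError(
                "labs.csv: wrong unit for analyte",
                rows=labs.index[bad_unit].tolist())
        if (labs["value"] <= 0).any():
            raise BundleValidationError(
                "labs.csv: non-positive value",
                rows=labs.index[labs["value"] <= 0].tolist())
        key = labs[["patient_id", "date", "analyte"]]
        dup = key.duplicated()
        if dup.any():
            raise BundleValidationError(
                "labs.csv: duplicate (patient_id, date, analyte)",
                rows=labs.index[dup].tolist())
    if len(sessions):
        sessions = _parse_dates(sessions, "session_date", "sessions.csv")
    return BundleData(patients=patients, labs=labs, sessions=sessions)


def write_bundle(bundle, path) -> None:
    """Write a cohort bundle (observables, ground-truth sidecar, spec echo)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.patients.to_csv(path / "patients.csv", index=False)
    bundle.labs.to_csv(path / "labs.csv", index=False)
    bundle.sessions.to_csv(path / "sessions.csv", index=False)
    if getattr(bundle, "truth", None):
        rows, daily = [], []
        for pid, tr in bundle.truth.items():
            row = {"patient_id": pid,
                   "session_pre": tr.session_pre,
                   "session_post": tr.session_post}
            row.update({f"param_{k}": v for k, v in
                        dataclasses.asdict(tr.params).items()})
            rows.append(row)
            d = tr.daily.copy()
            d.insert(0, "patient_id", pid)
            daily.append(d)
        pd.DataFrame(rows).to_csv(path / "truth_params.csv", index=False)
        pd.concat(daily, ignore_index=True).to_csv(
            path / "truth_daily.csv", index=False)
    if getattr(bundle, "spec", None) is not None:
        import yaml
        with open(path / "spec_echo.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(bundle.spec), fh,
                           sort_keys=True)


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

def write_params(params: PTGParameters, path) -> None:
    """Serialize one parameter set as flat ``key = value`` text."""
    with open(path, "w") as fh:
        for key, value in dataclasses.asdict(params).items():
            fh.write(f"{key} = {value!r}\n")


def read_params(path) -> PTGParameters:
    fields = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise BundleValidationError(
                    f"{path}: malformed parameter line", rows=[lineno])
            key, _, value = line.partition("=")
            fields[key.strip()] = float(value.strip())
    try:
        return PTGParameters(**fields)
    except TypeError as exc:
        raise BundleValidationError(f"{path}: {exc}") from exc
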