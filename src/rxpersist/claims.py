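"""Claims-table data model: schemas, date conventions, readers and writers.

The package operates on four flat tables that emulate the layout of a
Japanese employment-based health-insurance claims extract:

* ``enrollment``    — one row per beneficiary: id, birth year-month, sex and
  the observable enrollment window.
* ``prescriptions`` — outpatient drug dispensings with an ATC code and a
  days-of-supply field (1–90 days, the permitted range in Japan).
* ``diagnoses``     — ICD-10 coded diagnoses with a "suspected diagnosis"
  flag (tentative diagnoses recorded for billing, to be excluded from
  comorbidity ascertainment).
* ``visits``        — one row per outpatient claim; each claim represents one
  outpatient visit.

Date convention
---------------
Some source fields (birthday, enrollment window, outpatient-visit dates) are
stored at month resolution as six digits ``YYYYMM``.  Such dates are imputed
to day 15 of the month; eight-digit ``YYYYMMDD`` values parse literally.
All downstream window arithmetic is in integer days over half-open
``[start, end)`` intervals.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, fields
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ATC_ANTIDIABETIC",
    "ATC_SGLT2I",
    "BundleValidationError",
    "ClaimsBundle",
    "ClaimsError",
    "DateParseError",
    "IMPUTED_DAY",
    "format_claim_date",
    "parse_claim_date",
    "parse_date_series",
    "read_bundle",
    "write_bundle",
]

#: ATC prefix covering all antidiabetic agents.
ATC_ANTIDIABETIC = "A10"
#: ATC prefix for sodium-glucose co-transporter 2 inhibitors in the source coding.
ATC_SGLT2I = "A10P"

#: Day of month substituted for month-resolution (six digit) dates.
IMPUTED_DAY = 15

DATE_MIN = _dt.date(1900, 1, 1)
DATE_MAX = _dt.date(2100, 12, 31)

SEXES = ("male", "female")

ENROLLMENT_COLUMNS = ("patient_id", "birth_ym", "sex", "obs_start", "obs_end")
PRESCRIPTION_COLUMNS = ("patient_id", "rx_date", "atc_code", "days_supply", "fdc_flag")
DIAGNOSIS_COLUMNS = ("patient_id", "dx_date", "icd10_code", "suspected_flag")
VISIT_COLUMNS = ("patient_id", "visit_date")

TABLE_FILES = {
    "enrollment": "enrollment.csv",
    "prescriptions": "prescriptions.csv",
    "diagnoses": "diagnoses.csv",
    "visits": "visits.csv",
}


class ClaimsError(ValueError):
    """Base class for claims-model errors."""


class DateParseError(ClaimsError):
    """A claim date string could not be parsed."""


class BundleValidationError(ClaimsError):
    """A claims bundle violated a schema or referential-integrity invariant."""


# ---------------------------------------------------------------------------
# Dates


@lru_cache(maxsize=200_000)
def parse_claim_date(raw: str) -> _dt.date:
    """Parse a six- or eight-digit claim date string.

    Six digits (``YYYYMM``) denote a month-resolution date and are imputed to
    day 15 of that month; eight digits (``YYYYMMDD``) parse literally.

    >>> parse_claim_date("202208")
    datetime.date(2022, 8, 15)
    >>> parse_claim_date("20220815")
    datetime.date(2022, 8, 15)
    """
    s = str(raw).strip()
    if not s.isdigit() or len(s) not in (6, 8):
        raise DateParseError(
            f"claim date must be a 6-digit YYYYMM or 8-digit YYYYMMDD string, got {raw!r}"
        )
    year, month = int(s[:4]), int(s[4:6])
    day = int(s[6:8]) if len(s) == 8 else IMPUTED_DAY
    if not 1 <= month <= 12:
        raise DateParseError(f"month out of range in claim date {raw!r}")
    try:
        value = _dt.date(year, month, day)
    except ValueError as exc:
        raise DateParseError(f"invalid day in claim date {raw!r}") from exc
    if not DATE_MIN <= value <= DATE_MAX:
        raise DateParseError(f"claim date {raw!r} outside supported range 1900-2100")
    return value


def format_claim_date(value) -> str:
    """Render a date as its canonical eight-digit string."""
    value = pd.Timestamp(value)
    return f"{value.year:04d}{value.month:02d}{value.day:02d}"


def parse_date_series(series: pd.Series, *, context: str = "date") -> pd.Series:
    """Parse a column of 6/8-digit date strings into ``datetime64[ns]``.

    Raises :class:`DateParseError` naming the first offending row.
    """
    out = []
    for idx, raw in series.items():
        try:
            out.append(parse_claim_date(raw))
        except DateParseError as exc:
            raise DateParseError(f"{context}, row {idx}: {exc}") from exc
    return pd.Series(pd.to_datetime(out), index=series.index)


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class ClaimsBundle:
    """The four claims tables for one population, keyed by ``patient_id``.

    Date columns hold ``datetime64[ns]`` values after parsing; ``birth_ym``
    stays a six-digit string (its day is imputed on demand).
    """

    enrollment: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    visits: pd.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.enrollment)

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.enrollment.copy(),
            self.prescriptions.copy(),
            self.diagnoses.copy(),
            self.visits.copy(),
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ClaimsBundle":
        """Enforce schema, range and referential-integrity invariants.

        Raises :class:`BundleValidationError` listing offending rows.
        Returns ``self`` for chaining.
        """
        problems: list[str] = []
        self._check_columns(problems)
        if problems:
            raise BundleValidationError("; ".join(problems))

        enr = self.enrollment
        if enr["patient_id"].duplicated().any():
            dups = enr.loc[enr["patient_id"].duplicated(), "patient_id"].tolist()[:5]
            problems.append(f"duplicate patient_id in enrollment: {dups}")
        bad_sex = ~enr["sex"].isin(SEXES)
        if bad_sex.any():
            problems.append(
                f"enrollment rows with unknown sex: {list(enr.index[bad_sex])[:10]}"
            )
        bad_window = enr["obs_start"] > enr["obs_end"]
        if bad_window.any():
            problems.append(
                f"enrollment rows with obs_start > obs_end: {list(enr.index[bad_window])[:10]}"
            )
        # Beneficiaries leave the source system at age 75: age must stay
        # below 75 throughout the observable window.
        birth = parse_date_series(enr["birth_ym"], context="enrollment.birth_ym")
        age_cap = birth + pd.DateOffset(years=75)
        over = enr["obs_end"] >= pd.to_datetime(age_cap)
        if over.any():
            problems.append(
                f"enrollment rows observed at age >= 75: {list(enr.index[over])[:10]}"
            )

        known = set(enr["patient_id"])
        rx = self.prescriptions
        bad_supply = ~rx["days_supply"].between(1, 90)
        if bad_supply.any():
            problems.append(
                f"prescriptions with days_supply outside 1..90: {list(rx.index[bad_supply])[:10]}"
            )
        empty_atc = rx["atc_code"].astype(str).str.len() == 0
        if empty_atc.any():
            problems.append(
                f"prescriptions with empty atc_code: {list(rx.index[empty_atc])[:10]}"
            )
        dx = self.diagnoses
        bad_icd = ~dx["icd10_code"].astype(str).str.match(r"^[A-Z][0-9]{2,5}$")
        if bad_icd.any():
            problems.append(
                f"diagnoses with malformed ICD-10 code: {list(dx.index[bad_icd])[:10]}"
            )

        for name, table, date_col in (
            ("prescriptions", rx, "rx_date"),
            ("diagnoses", dx, "dx_date"),
            ("visits", self.visits, "visit_date"),
        ):
            orphan = ~table["patient_id"].isin(known)
            if orphan.any():
                problems.append(
                    f"{name} rows for unknown patient_id: {list(table.index[orphan])[:10]}"
                )
                continue
            merged = table[["patient_id", date_col]].merge(
                enr[["patient_id", "obs_start", "obs_end"]], on="patient_id", how="left"
            )
            outside = (merged[date_col] < merged["obs_start"]) | (
                merged[date_col] > merged["obs_end"]
            )
            if outside.any():
                problems.append(
                    f"{name} rows dated outside enrollment: {list(table.index[np.asarray(outside)])[:10]}"
                )

        if problems:
            raise BundleValidationError("; ".join(problems))
        return self

    def _check_columns(self, problems: list[str]) -> None:
        for name, cols in (
            ("enrollment", ENROLLMENT_COLUMNS),
            ("prescriptions", PRESCRIPTION_COLUMNS),
            ("diagnoses", DIAGNOSIS_COLUMNS),
            ("visits", VISIT_COLUMNS),
        ):
            table = getattr(self, name)
            missing = [c for c in cols if c not in table.columns]
            if missing:
                problems.append(f"{name} missing column(s) {missing}")


# ---------------------------------------------------------------------------
# I/O

_BOOL_MAP = {
    "0": False,
    "1": True,
    "false": False,
    "true": True,
}


def _parse_bool(series: pd.Series, context: str) -> pd.Series:
    vals = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if vals.isna().any():
        bad = series[vals.isna()].head(5).tolist()
        raise BundleValidationError(f"{context}: unparseable boolean values {bad}")
    return vals.astype(bool)


def read_bundle(paths: Path | str | Mapping[str, Path | str], *, sep: str = ",") -> ClaimsBundle:
    """Read and validate the four claims tables.

    Parameters
    ----------
    paths
        Either a directory holding ``enrollment.csv``, ``prescriptions.csv``,
        ``diagnoses.csv`` and ``visits.csv``, or a mapping from table name to
        file path.
    sep
        Field delimiter.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        files = {name: root / fname for name, fname in TABLE_FILES.items()}
    else:
        files = {name: Path(p) for name, p in paths.items()}
    for name in TABLE_FILES:
        if name not in files:
            raise BundleValidationError(f"no path given for table {name!r}")
        if not files[name].exists():
            raise BundleValidationError(f"missing table file: {files[name]}")

    def _read(name: str) -> pd.DataFrame:
        df = pd.read_csv(files[name], sep=sep, dtype=str, keep_default_na=False)
        logger.info("read %s: %d rows", files[name], len(df))
        return df

    enr = _read("enrollment")
    rx = _read("prescriptions")
    dx = _read("diagnoses")
    vis = _read("visits")

    bundle = ClaimsBundle(enr, rx, dx, vis)
    problems: list[str] = []
    bundle._check_columns(problems)
    if problems:
        raise BundleValidationError("; ".join(problems))

    enr = enr.assign(
        obs_start=parse_date_series(enr["obs_start"], context="enrollment.obs_start"),
        obs_end=parse_date_series(enr["obs_end"], context="enrollment.obs_end"),
    )
    rx = rx.assign(
        rx_date=parse_date_series(rx["rx_date"], context="prescriptions.rx_date"),
        atc_code=rx["atc_code"].str.strip().str.upper(),
        days_supply=pd.to_numeric(rx["days_supply"], errors="raise").astype(int),
        fdc_flag=_parse_bool(rx["fdc_flag"], "prescriptions.fdc_flag"),
    )
    dx = dx.assign(
        dx_date=parse_date_series(dx["dx_date"], context="diagnoses.dx_date"),
        icd10_code=dx["icd10_code"].str.strip().str.upper().str.replace(".", "", regex=False),
        suspected_flag=_parse_bool(dx["suspected_flag"], "diagnoses.suspected_flag"),
    )
    vis = vis.assign(
        visit_date=parse_date_series(vis["visit_date"], context="visits.visit_date")
    )
    return ClaimsBundle(enr, rx, dx, vis).validate()


def write_bundle(bundle: ClaimsBundle, directory: Path | str, *, sep: str = ",") -> dict[str, Path]:
    """Write the four tables as delimited text; dates as 8-digit strings.

    Returns the mapping of table name to written path.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    enr = bundle.enrollment.copy()
    enr["obs_start"] = enr["obs_start"].map(format_claim_date)
    enr["obs_end"] = enr["obs_end"].map(format_claim_date)
    rx = bundle.prescriptions.copy()
    rx["rx_date"] = rx["rx_date"].map(format_claim_date)
    rx["fdc_flag"] = rx["fdc_flag"].astype(int)
    dx = bundle.diagnoses.copy()
    dx["dx_date"] = dx["dx_date"].map(format_claim_date)
    dx["suspected_flag"] = dx["suspected_flag"].astype(int)
    vis = bundle.visits.copy()
    vis["visit_date"] = vis["visit_date"].map(format_claim_date)

    for name, frame, cols in (
        ("enrollment", enr, ENROLLMENT_COLUMNS),
        ("prescriptions", rx, PRESCRIPTION_COLUMNS),
        ("diagnoses", dx, DIAGNOSIS_COLUMNS),
        ("visits", vis, VISIT_COLUMNS),
    ):
        path = root / TABLE_FILES[name]
        frame.loc[:, list(cols)].to_csv(path, sep=sep, index=False)
        out[name] = path
    return out


def birth_date_series(enrollment: pd.DataFrame) -> pd.Series:
    """Birth dates with the day-15 imputation applied to ``birth_ym``."""
    return parse_date_series(enrollment["birth_ym"], context="enrollment.birth_ym")
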