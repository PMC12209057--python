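"""Baseline covariates from the 180-day pre-index window.

For every cohort member this module derives: calendar year at index, sex,
fractional age, outpatient-visit count and mean inter-visit interval,
number of concomitant cardiometabolic drug classes (renin-angiotensin
system agents C09, beta blockers C07, calcium channel blockers C08,
diuretics C03, lipid-lowering agents C10), six comorbidity flags from
ICD-10 prefixes, and the Charlson comorbidity index.  Suspected-diagnosis
flags are excluded from all diagnosis-based measures, and everything except
calendar year, age and sex is ascertained strictly within the pre-index
window ``[index - 180, index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cci
from .claims import ClaimsBundle

__all__ = [
    "CodeMap",
    "DEFAULT_CODE_MAP",
    "flag_comorbidity",
    "count_concomitant_classes",
    "visit_stats",
    "compute_cci",
    "build_covariates",
]

COMORBIDITY_NAMES = (
    "hypertension",
    "dyslipidemia",
    "depression",
    "obesity",
    "hyperuricemia",
    "nephropathy",
)


@dataclass(frozen=True)
class CodeMap:
    """ICD-10 prefixes per comorbidity and ATC prefixes per drug class.

    The default assigns hypertension=I10 and dyslipidemia=E78, the
    conventional ICD-10 semantics (lexically, E78 is a lipoprotein-disorder
    code); both maps are overridable for sources with other conventions.
    """

    comorbidities: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "hypertension": ("I10",),
            "dyslipidemia": ("E78",),
            "depression": ("F32", "F33"),
            "obesity": ("E66",),
            "hyperuricemia": ("E790",),
            "nephropathy": ("E112", "E142", "N083", "N189"),
        }
    )
    drug_classes: dict[str, str] = field(
        default_factory=lambda: {
            "ras_agents": "C09",
            "beta_blockers": "C07",
            "calcium_channel_blockers": "C08",
            "diuretics": "C03",
            "lipid_lowering": "C10",
        }
    )

    def with_comorbidity(self, name: str, prefixes: tuple[str, ...]) -> "CodeMap":
        updated = dict(self.comorbidities)
        updated[name] = prefixes
        return replace(self, comorbidities=updated)


DEFAULT_CODE_MAP = CodeMap()


def _normalise(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.upper().str.replace(".", "", regex=False)


def flag_comorbidity(
    diagnoses: pd.DataFrame,
    prefixes: tuple[str, ...],
    index_date,
    *,
    pre_days: int = 180,
) -> bool:
    """True iff one patient has >= 1 non-suspected diagnosis matching any
    prefix within ``[index - pre_days, index)``."""
    if diagnoses.empty:
        return False
    rel = (diagnoses["dx_date"] - pd.Timestamp(index_date)).dt.days
    in_window = (rel >= -pre_days) & (rel < 0) & ~diagnoses["suspected_flag"]
    codes = _normalise(diagnoses.loc[in_window, "icd10_code"])
    return bool(codes.str.startswith(tuple(prefixes)).any())


def count_concomitant_classes(
    prescriptions: pd.DataFrame,
    index_date,
    *,
    pre_days: int = 180,
    code_map: CodeMap = DEFAULT_CODE_MAP,
) -> int:
    """Distinct concomitant drug classes with >= 1 pre-index fill.

    Fixed-dose combination products count toward every class they match.
    """
    if prescriptions.empty:
        return 0
    rel = (prescriptions["rx_date"] - pd.Timestamp(index_date)).dt.days
    codes = prescriptions.loc[(rel >= -pre_days) & (rel < 0), "atc_code"].str.upper()
    return sum(codes.str.startswith(prefix).any() for prefix in code_map.drug_classes.values())


def visit_stats(
    visits: pd.DataFrame, index_date, *, pre_days: int = 180
) -> tuple[int, float]:
    """Pre-index visit count and mean inter-visit interval in days.

    Every claim counts one visit; the interval is computed over *distinct*
    visit dates as ``(last - first) / (n_distinct - 1)``.  When all claims
    collapse onto a single (possibly month-imputed) date the interval is
    0.0.  Fewer than two pre-index visits violates the cohort contract.
    """
    rel = (visits["visit_date"] - pd.Timestamp(index_date)).dt.days
    days = rel[(rel >= -pre_days) & (rel < 0)]
    n = int(len(days))
    if n < 2:
        raise ValueError("cohort member with < 2 pre-index visits")
    distinct = np.unique(days.to_numpy())
    if distinct.size == 1:
        return n, 0.0
    return n, float((distinct[-1] - distinct[0]) / (distinct.size - 1))


def compute_cci(diagnoses: pd.DataFrame, index_date, *, pre_days: int = 180) -> int:
    """Charlson comorbidity index over pre-index, non-suspected diagnoses."""
    if diagnoses.empty:
        return 0
    rel = (diagnoses["dx_date"] - pd.Timestamp(index_date)).dt.days
    in_window = (rel >= -pre_days) & (rel < 0) & ~diagnoses["suspected_flag"]
    return cci.charlson_index(_normalise(diagnoses.loc[in_window, "icd10_code"]))


def build_covariates(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    *,
    code_map: CodeMap = DEFAULT_CODE_MAP,
    pre_days: int = 180,
) -> pd.DataFrame:
    """Covariate vector for every cohort member (vectorised over patients).

    Output columns: ``patient_id, calendar_year_2018, sex_male, age_years,
    n_visits, mean_visit_interval_days, n_concomitant_classes`` + one boolean
    per comorbidity + ``cci``.
    """
    base = cohort[["patient_id", "index_date", "calendar_year", "age_at_index", "sex"]]
    out = pd.DataFrame(
        {
            "patient_id": base["patient_id"].to_numpy(),
            "calendar_year_2018": (base["calendar_year"] == 2018).to_numpy(),
            "sex_male": (base["sex"] == "male").to_numpy(),
            "age_years": base["age_at_index"].to_numpy(),
        }
    )
    key = base[["patient_id", "index_date"]]

    # diagnoses restricted to the pre-index window, suspected flags dropped
    dx = bundle.diagnoses.merge(key, on="patient_id", how="inner")
    rel = (dx["dx_date"] - dx["index_date"]).dt.days
    dx = dx[(rel >= -pre_days) & (rel < 0) & ~dx["suspected_flag"]]
    dx_codes = _normalise(dx["icd10_code"])

    for name in COMORBIDITY_NAMES:
        prefixes = tuple(code_map.comorbidities[name])
        hit = dx.loc[dx_codes.str.startswith(prefixes), "patient_id"].unique()
        out[name] = out["patient_id"].isin(hit).to_numpy()

    cci_scores = (
        pd.DataFrame({"patient_id": dx["patient_id"], "code": dx_codes})
        .groupby("patient_id")["code"]
        .apply(cci.charlson_index)
    )
    out["cci"] = out["patient_id"].map(cci_scores).fillna(0).astype(int).to_numpy()

    # concomitant drug classes
    rx = bundle.prescriptions.merge(key, on="patient_id", how="inner")
    rrel = (rx["rx_date"] - rx["index_date"]).dt.days
    rx = rx[(rrel >= -pre_days) & (rrel < 0)]
    atc = rx["atc_code"].str.upper()
    n_classes = np.zeros(len(out), dtype=int)
    for name, prefix in code_map.drug_classes.items():
        hit = rx.loc[atc.str.startswith(prefix), "patient_id"].unique()
        flag = out["patient_id"].isin(hit).to_numpy()
        out[f"rx_{name}"] = flag
        n_classes += flag.astype(int)
    out["n_concomitant_classes"] = n_classes

    # visit counts and intervals
    vis = bundle.visits.merge(key, on="patient_id", how="inner")
    vrel = (vis["visit_date"] - vis["index_date"]).dt.days
    vis = vis.assign(day=vrel)[(vrel >= -pre_days) & (vrel < 0)]
    grouped = vis.groupby("patient_id")["day"]
    n_visits = grouped.size()
    n_distinct = grouped.nunique()
    span = grouped.max() - grouped.min()
    interval = (span / (n_distinct - 1).clip(lower=1)).where(n_distinct > 1, 0.0)

    out["n_visits"] = out["patient_id"].map(n_visits).fillna(0).astype(int).to_numpy()
    out["mean_visit_interval_days"] = (
        out["patient_id"].map(interval).astype(float).to_numpy()
    )
    if (out["n_visits"] < 2).any():
        bad = out.loc[out["n_visits"] < 2, "patient_id"].tolist()[:5]
        raise ValueError(f"cohort members with < 2 pre-index visits: {bad}")
    return out
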