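"""New-user cohort construction with an auditable exclusion cascade.

A new user is a patient whose first SGLT2i fill (the index date) is preceded
by a 180-day washout free of any antidiabetic prescription, with enrollment
covering both the 180-day pre-index and the 365-day post-index window.
Candidates then pass an ordered exclusion cascade: data-quality (missing
prescription date), a single SGLT2i prescription in follow-up, combination
therapy at the index date, a fixed-dose-combination SGLT2i product at index,
and fewer than two pre-index outpatient visits.  Every stage is recorded in
a flow-count table so the selection funnel can be audited.

The source extract is assumed to be restricted to type-2-diabetes patients
already; no diagnosis re-check is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims import ATC_ANTIDIABETIC, ATC_SGLT2I, ClaimsBundle, birth_date_series

__all__ = ["FlowCounts", "identify_new_users", "apply_exclusions", "build_cohort"]

PRE_INDEX_DAYS = 180
POST_INDEX_DAYS = 365

COHORT_COLUMNS = ("patient_id", "index_date", "calendar_year", "age_at_index", "sex")

#: labelled exclusion stages, in the order they are applied
EXCLUSION_STAGES = (
    ("missing_rx_date", "antidiabetic prescription with no prescription date"),
    ("single_sglt2i_rx", "only one SGLT2i prescription in the post-index period"),
    ("combination_at_index", "another antidiabetic agent prescribed on the index date"),
    ("fdc_at_index", "fixed-dose combination SGLT2i product at the index date"),
    ("lt2_pre_visits", "fewer than two outpatient visits in the pre-index period"),
)


@dataclass
class FlowCounts:
    """Ordered selection-funnel counts: (stage label, n remaining, n excluded)."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, label: str, n_remaining: int, n_excluded: int) -> None:
        if n_remaining < 0 or n_excluded < 0:
            raise ValueError("flow counts must be non-negative")
        if self.stages:
            prev_remaining = self.stages[-1][1]
            if prev_remaining - n_excluded != n_remaining:
                raise ValueError(
                    f"flow not conserved at {label!r}: "
                    f"{prev_remaining} - {n_excluded} != {n_remaining}"
                )
        self.stages.append((label, n_remaining, n_excluded))

    @property
    def final_n(self) -> int:
        return self.stages[-1][1] if self.stages else 0

    def combined(self, labels: tuple[str, ...]) -> int:
        """Total excluded across a group of stages (e.g. both combination stages)."""
        return sum(e for lab, _, e in self.stages if lab in labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_remaining", "n_excluded"])


def identify_new_users(
    bundle: ClaimsBundle,
    *,
    pre_days: int = PRE_INDEX_DAYS,
    post_days: int = POST_INDEX_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate new users: first SGLT2i fill with clean washout and full windows.

    The candidate index date is the patient's first SGLT2i prescription; a
    patient qualifies only if enrollment spans ``[index - pre_days,
    index + post_days)`` and no antidiabetic fill (any ATC A10) falls in the
    washout ``[index - pre_days, index)``.  Later fills are never promoted to
    index events, so restarters cannot re-enter as new users.

    Returns ``(candidates, rejected)``; ``rejected`` carries a ``reason``
    column (``no_sglt2i``, ``insufficient_enrollment``, ``prior_antidiabetic``).
    """
    rx = bundle.prescriptions
    a10 = rx[rx["atc_code"].str.startswith(ATC_ANTIDIABETIC)]
    sglt2i = a10[a10["atc_code"].str.startswith(ATC_SGLT2I)]

    first = (
        sglt2i.sort_values("rx_date")
        .groupby("patient_id", as_index=False)
        .first()[["patient_id", "rx_date"]]
        .rename(columns={"rx_date": "index_date"})
    )
    cand = first.merge(bundle.enrollment, on="patient_id", how="left")

    rejected: list[tuple[str, str]] = []
    no_sglt2i = bundle.enrollment.loc[
        ~bundle.enrollment["patient_id"].isin(first["patient_id"]), "patient_id"
    ]
    rejected += [(pid, "no_sglt2i") for pid in no_sglt2i]

    covers = (cand["obs_start"] <= cand["index_date"] - pd.Timedelta(days=pre_days)) & (
        cand["obs_end"] >= cand["index_date"] + pd.Timedelta(days=post_days - 1)
    )
    rejected += [(pid, "insufficient_enrollment") for pid in cand.loc[~covers, "patient_id"]]
    cand = cand[covers]

    washout = a10.merge(
        cand[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    rel = (washout["rx_date"] - washout["index_date"]).dt.days
    prior = washout.loc[(rel >= -pre_days) & (rel < 0), "patient_id"].unique()
    rejected += [(pid, "prior_antidiabetic") for pid in prior]
    cand = cand[~cand["patient_id"].isin(prior)]

    candidates = cand[["patient_id", "index_date", "birth_ym", "sex"]].reset_index(drop=True)
    rejected_df = pd.DataFrame(rejected, columns=["patient_id", "reason"])
    return candidates, rejected_df


def apply_exclusions(
    candidates: pd.DataFrame,
    bundle: ClaimsBundle,
    *,
    pre_days: int = PRE_INDEX_DAYS,
    post_days: int = POST_INDEX_DAYS,
    flow: FlowCounts | None = None,
) -> tuple[pd.DataFrame, FlowCounts]:
    """Apply the labelled exclusion cascade to new-user candidates.

    Returns the analytic cohort (one row per included patient with index
    date, calendar year, fractional age and sex) and the flow counts.
    """
    if flow is None:
        flow = FlowCounts()
        flow.add("new_user_candidates", len(candidates), 0)

    rx = bundle.prescriptions.merge(
        candidates[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    rx["day"] = (rx["rx_date"] - rx["index_date"]).dt.days
    a10 = rx[rx["atc_code"].str.startswith(ATC_ANTIDIABETIC)]
    is_sglt2i = a10["atc_code"].str.startswith(ATC_SGLT2I)

    post = a10[is_sglt2i & (a10["day"] >= 0) & (a10["day"] < post_days)]
    n_post = post.groupby("patient_id").size()

    missing_date = a10.loc[a10["rx_date"].isna(), "patient_id"].unique()
    single_rx = set(n_post[n_post == 1].index)
    combo = set(
        a10.loc[~is_sglt2i & (a10["day"] == 0), "patient_id"].unique()
    )
    fdc = set(
        post.loc[(post["day"] == 0) & post["fdc_flag"], "patient_id"].unique()
    )
    vis = bundle.visits.merge(
        candidates[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    vday = (vis["visit_date"] - vis["index_date"]).dt.days
    n_pre_visits = vis[(vday >= -pre_days) & (vday < 0)].groupby("patient_id").size()
    few_visits = set(candidates["patient_id"]) - set(n_pre_visits[n_pre_visits >= 2].index)

    stage_sets = {
        "missing_rx_date": set(missing_date),
        "single_sglt2i_rx": single_rx,
        "combination_at_index": combo,
        "fdc_at_index": fdc,
        "lt2_pre_visits": few_visits,
    }

    remaining = candidates
    for label, _desc in EXCLUSION_STAGES:
        hit = remaining["patient_id"].isin(stage_sets[label])
        flow.add(label, int((~hit).sum()) + 0, int(hit.sum()))
        remaining = remaining[~hit]

    birth = birth_date_series(remaining)
    age = (remaining["index_date"] - birth).dt.days / 365.25
    cohort = pd.DataFrame(
        {
            "patient_id": remaining["patient_id"].to_numpy(),
            "index_date": remaining["index_date"].to_numpy(),
            "calendar_year": remaining["index_date"].dt.year.to_numpy(),
            "age_at_index": age.to_numpy(),
            "sex": remaining["sex"].to_numpy(),
        }
    )
    flow.add("final_cohort", len(cohort), 0)
    return cohort, flow


def build_cohort(
    bundle: ClaimsBundle,
    *,
    pre_days: int = PRE_INDEX_DAYS,
    post_days: int = POST_INDEX_DAYS,
) -> tuple[pd.DataFrame, FlowCounts]:
    """Full funnel: total population → new-user candidates → analytic cohort."""
    flow = FlowCounts()
    flow.add("total_patients", bundle.n_patients, 0)
    candidates, rejected = identify_new_users(bundle, pre_days=pre_days, post_days=post_days)
    flow.add(
        "new_user_candidates",
        len(candidates),
        bundle.n_patients - len(candidates),
    )
    return apply_exclusions(
        candidates, bundle, pre_days=pre_days, post_days=post_days, flow=flow
    )
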