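"""Per-patient persistence and adherence over the post-index follow-up.

Persistence is measured with a permissible-gap rule on prescription dates:
the first pair of consecutive index-drug fills whose date-to-date gap
*exceeds* the permissible gap (90 days primary, 30 days in sensitivity
analyses) marks a discontinuation, dated at the earlier fill's supply
run-out (capped at the end of follow-up).  A trailing gap — no further fill
and more than the permissible gap left before day 365 — counts the same
way.  Starting any other antidiabetic agent after the index date ends
monotherapy persistence on that fill's date ("switch").  The earliest event
wins; patients with no event are censored persistent at day 365.

Adherence is the proportion of days covered (PDC): the union of supply
intervals within the fixed 365-day window divided by 365, overlapping
supply counted once, gaps ignored.  PDC >= 0.80 defines adherent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import ATC_ANTIDIABETIC, ATC_SGLT2I, ClaimsBundle

__all__ = [
    "GapPolicy",
    "covered_days",
    "detect_discontinuation",
    "detect_restart",
    "compute_exposure",
]

EXPOSURE_COLUMNS = (
    "patient_id",
    "persistence_days",
    "discontinued",
    "reason",
    "restarted",
    "covered_days",
    "pdc",
    "adherent",
)


@dataclass(frozen=True)
class GapPolicy:
    """Permissible-gap rule parameters.

    permissible_gap
        Largest allowed date-to-date gap in days; a strictly larger gap is a
        discontinuation event (a gap of exactly ``permissible_gap`` days is
        tolerated).
    followup_days
        Fixed follow-up horizon; also the PDC denominator.
    pdc_threshold
        Adherence cut-off on PDC.
    """

    permissible_gap: int = 90
    followup_days: int = 365
    pdc_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.permissible_gap < 1:
            raise ValueError("permissible_gap must be >= 1 day")
        if self.followup_days < 1:
            raise ValueError("followup_days must be >= 1 day")
        if not 0 < self.pdc_threshold < 1:
            raise ValueError("pdc_threshold must be in (0, 1)")


def covered_days(
    fill_days: np.ndarray,
    supplies: np.ndarray,
    followup_days: int = 365,
    *,
    _warn: bool = True,
) -> int:
    """Days covered by the union of supply intervals within the window.

    Each fill covers the half-open interval ``[day, day + supply)``; the
    union is intersected with ``[0, followup_days)`` so overlapping (early)
    refills are never double-counted and there is no stockpiling shift.
    Fills dated outside the window are ignored (with a warning).
    """
    fill_days = np.asarray(fill_days, dtype=np.int64)
    supplies = np.asarray(supplies, dtype=np.int64)
    if fill_days.shape != supplies.shape:
        raise ValueError("fill_days and supplies must align")
    inside = (fill_days >= 0) & (fill_days < followup_days)
    if _warn and not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} fill(s) outside [0, {followup_days}) ignored",
            stacklevel=2,
        )
    fill_days, supplies = fill_days[inside], supplies[inside]
    if fill_days.size == 0:
        return 0
    order = np.argsort(fill_days, kind="stable")
    covered = 0
    reach = 0  # first day not yet covered by any earlier interval
    for day, supply in zip(fill_days[order], supplies[order]):
        end = min(day + supply, followup_days)
        start = max(day, reach)
        if end > start:
            covered += end - start
            reach = end
    return int(covered)


def detect_discontinuation(
    fill_days: np.ndarray,
    supplies: np.ndarray,
    other_fill_days: np.ndarray,
    policy: GapPolicy = GapPolicy(),
) -> tuple[int, bool, str]:
    """First discontinuation event for one patient.

    Parameters are day offsets from the index date: index-drug fills (sorted,
    with supplies) and fills of other drugs of the class (monotherapy-ending
    switches).  Returns ``(persistence_days, discontinued, reason)`` with
    reason one of ``gap``, ``switch``, ``none``.
    """
    fill_days = np.asarray(fill_days, dtype=np.int64)
    supplies = np.asarray(supplies, dtype=np.int64)
    other_fill_days = np.asarray(other_fill_days, dtype=np.int64)
    if fill_days.size == 0:
        raise ValueError("patient has no index-drug fill: cohort precondition violated")
    if np.any(np.diff(fill_days) < 0):
        raise ValueError("fill_days must be sorted ascending")
    horizon = policy.followup_days
    gap = policy.permissible_gap

    gap_day: int | None = None
    diffs = np.diff(fill_days)
    breaches = np.nonzero(diffs > gap)[0]
    if breaches.size:
        j = int(breaches[0])
        gap_day = int(min(fill_days[j] + supplies[j], horizon))
    elif horizon - fill_days[-1] > gap:
        gap_day = int(min(fill_days[-1] + supplies[-1], horizon))

    switch_candidates = other_fill_days[(other_fill_days > 0) & (other_fill_days < horizon)]
    switch_day = int(switch_candidates.min()) if switch_candidates.size else None

    # earliest event wins; on a tie the gap is attributed (supply had
    # already run out when the other agent was started)
    if gap_day is not None and (switch_day is None or gap_day <= switch_day):
        return gap_day, True, "gap"
    if switch_day is not None:
        return switch_day, True, "switch"
    return horizon, False, "none"


def detect_restart(
    fill_days: np.ndarray, event_day: int | None, followup_days: int = 365
) -> bool:
    """True iff any index-drug fill falls strictly after the gap event day
    and before the end of follow-up."""
    if event_day is None:
        raise ValueError("detect_restart called for a patient with no discontinuation")
    fill_days = np.asarray(fill_days, dtype=np.int64)
    return bool(np.any((fill_days > event_day) & (fill_days < followup_days)))


def compute_exposure(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    policy: GapPolicy = GapPolicy(),
    *,
    restart_after_switch: bool = False,
) -> pd.DataFrame:
    """Assemble persistence and adherence results for every cohort member.

    ``cohort`` needs ``patient_id`` and ``index_date`` columns.  Restart is
    evaluated only after gap discontinuations by default — a switcher is
    still on antidiabetic therapy; set ``restart_after_switch`` to also flag
    index-drug fills after a switch event.
    """
    if cohort.empty:
        return pd.DataFrame(columns=EXPOSURE_COLUMNS)

    rx = bundle.prescriptions.merge(
        cohort[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    rx["day"] = (rx["rx_date"] - rx["index_date"]).dt.days
    rx = rx[rx["atc_code"].str.startswith(ATC_ANTIDIABETIC)]
    is_index_drug = rx["atc_code"].str.startswith(ATC_SGLT2I)
    horizon = policy.followup_days

    own = rx[is_index_drug & (rx["day"] >= 0) & (rx["day"] < horizon)]
    other = rx[~is_index_drug & (rx["day"] > 0) & (rx["day"] < horizon)]

    own_groups = {
        pid: (g["day"].to_numpy(np.int64), g["days_supply"].to_numpy(np.int64))
        for pid, g in own.sort_values(["patient_id", "day"]).groupby("patient_id", sort=False)
    }
    other_groups = {
        pid: g["day"].to_numpy(np.int64)
        for pid, g in other.groupby("patient_id", sort=False)
    }
    empty = np.empty(0, dtype=np.int64)

    records = []
    for pid in cohort["patient_id"]:
        if pid not in own_groups:
            raise ValueError(
                f"cohort patient {pid!r} has no index-drug fill in the follow-up window"
            )
        days, supplies = own_groups[pid]
        persistence, discontinued, reason = detect_discontinuation(
            days, supplies, other_groups.get(pid, empty), policy
        )
        if discontinued and (reason == "gap" or restart_after_switch):
            restarted = detect_restart(days, persistence, horizon)
        else:
            restarted = False
        cov = covered_days(days, supplies, horizon, _warn=False)
        pdc = cov / horizon
        records.append(
            (pid, persistence, discontinued, reason, restarted, cov, pdc,
             pdc >= policy.pdc_threshold)
        )
    return pd.DataFrame(records, columns=EXPOSURE_COLUMNS)
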