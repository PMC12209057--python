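"""Synthetic claims generator with planted ground truth.

Emulates the structure of an employment-based Japanese claims extract for a
new-user drug-persistence study: enrollment windows over a three-year
observation period, SGLT2i refill sequences with configurable supply mix and
refill jitter, discontinuation with planted covariate effects, switches to
combination therapy, restart fills, pre-index comorbidity diagnoses and
concomitant cardiometabolic prescriptions at configurable prevalences, and
month-resolution (day-15 imputed) visit and diagnosis dates.

Outcome model
-------------
Each simulated initiator carries a latent 1-year non-persistence indicator
drawn from a logistic model: ``logit P(non-persistent) = logit(p0) + sum_k
beta_k (x_k - center_k)`` where ``p0 = 1 - (1 - h)^365`` comes from the
baseline per-day hazard ``h`` and the ``beta_k`` are the configured planted
log-odds.  Given non-persistence, the stop day is a truncated geometric
(per-day hazard ``h``) over the span in which a trailing permissible gap is
still observable within follow-up, and the patient either abandons refills
(gap mode, optionally restarting later) or starts a second antidiabetic
agent (switch mode).  Planting the effects on the binary outcome scale keeps
the planted log-odds identifiable by the downstream logistic analysis; the
per-day hazard still controls event timing for the survival analyses.

Every generated population ships with a truth table recording each
patient's branch, planted covariates, non-persistence status, stop day and
restart flag.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .claims import ClaimsBundle, parse_claim_date

__all__ = [
    "SimulationConfig",
    "generate",
    "make_worked_fixture",
    "WORKED_EXPECTED_BRANCH",
    "WORKED_EXPECTED_EXPOSURE",
]

SGLT2I_CODE = "A10PX01"
SGLT2I_FDC_CODE = "A10PF01"
METFORMIN_CODE = "A10BA02"
SULFONYLUREA_CODE = "A10BB01"

CONCOMITANT_CODES = {
    "ras_agents": "C09AA02",
    "beta_blockers": "C07AB03",
    "calcium_channel_blockers": "C08CA01",
    "diuretics": "C03CA01",
    "lipid_lowering": "C10AA07",
}

COMORBIDITY_DX_CODES = {
    "hypertension": "I10",
    "dyslipidemia": "E785",
    "depression": "F320",
    "obesity": "E669",
    "hyperuricemia": "E790",
    "nephropathy": "E112",
}

BRANCHES = (
    "none",
    "prior_antidiabetic",
    "short_enrollment",
    "combination_at_index",
    "fdc_at_index",
    "single_fill",
    "few_visits",
)


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate the source study population.

    Prevalences, age and sex mix come from the study's baseline table;
    the baseline hazard is set so cohort-level 1-year persistence lands
    near the observed 61%, and the planted log-odds default to the study's
    adjusted odds-ratio estimates.
    """

    n_patients: int = 2000
    seed: int = 0
    obs_start: _dt.date = _dt.date(2017, 10, 1)
    obs_end: _dt.date = _dt.date(2020, 9, 30)
    frac_new_users: float = 0.75
    #: days-of-supply mix (must be a valid probability vector; median 30)
    supply_days_distribution: dict[int, float] = field(
        default_factory=lambda: {14: 0.20, 30: 0.73, 60: 0.05, 90: 0.02}
    )
    refill_jitter_sd: float = 3.0
    #: chance a refill is late, and the uniform range of the extra delay (days)
    missed_refill_prob: float = 0.005
    missed_refill_delay: tuple[int, int] = (10, 55)
    #: baseline per-day discontinuation hazard
    discontinuation_hazard: float = 0.00147
    #: P(a non-persistent patient switches to combination therapy rather than quitting)
    switch_to_combination_prob: float = 0.08
    #: P(a gap discontinuer refills the index drug later in follow-up)
    restart_prob: float = 0.454
    #: planted log-odds on 1-year non-persistence; keys are covariate names
    #: (comorbidities, ``age_years`` per year, ``sex_male``, ``calendar_year_2018``)
    covariate_log_odds: dict[str, float] = field(
        default_factory=lambda: {
            "age_years": -0.033,
            "hypertension": -0.33,
            "dyslipidemia": -0.31,
            "hyperuricemia": -0.28,
        }
    )
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.611,
            "dyslipidemia": 0.651,
            "depression": 0.085,
            "obesity": 0.057,
            "hyperuricemia": 0.214,
            "nephropathy": 0.078,
        }
    )
    concomitant_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "ras_agents": 0.448,
            "beta_blockers": 0.129,
            "calcium_channel_blockers": 0.299,
            "diuretics": 0.094,
            "lipid_lowering": 0.483,
        }
    )
    #: extra Charlson-category diagnoses sprinkled into the pre-index window
    extra_charlson_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "I21": 0.02,   # myocardial infarction
            "I500": 0.03,  # congestive heart failure
            "J449": 0.04,  # chronic pulmonary disease
            "K259": 0.02,  # peptic ulcer
            "B182": 0.02,  # mild liver disease
        }
    )
    age_mean_sd: tuple[float, float] = (51.9, 9.1)
    male_frac: float = 0.734
    visit_rate_mean: float = 6.2
    suspected_noise_prob: float = 0.07
    # exclusion-branch mix among initiators
    frac_prior_antidiabetic: float = 0.10
    frac_short_enrollment: float = 0.04
    frac_combination_at_index: float = 0.05
    frac_fdc_at_index: float = 0.03
    frac_single_fill: float = 0.04
    frac_few_visits: float = 0.05

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.discontinuation_hazard < 0:
            raise ValueError("discontinuation_hazard must be >= 0")
        probs = [
            self.frac_new_users,
            self.switch_to_combination_prob,
            self.restart_prob,
            self.missed_refill_prob,
            self.suspected_noise_prob,
            self.male_frac,
            *self.comorbidity_prevalence.values(),
            *self.concomitant_prevalence.values(),
            *self.extra_charlson_prevalence.values(),
            self.frac_prior_antidiabetic,
            self.frac_short_enrollment,
            self.frac_combination_at_index,
            self.frac_fdc_at_index,
            self.frac_single_fill,
            self.frac_few_visits,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        weights = np.array(list(self.supply_days_distribution.values()), float)
        if weights.min() < 0 or not np.isclose(weights.sum(), 1.0):
            raise ValueError("supply_days_distribution must be a probability vector")
        branch_total = (
            self.frac_prior_antidiabetic + self.frac_short_enrollment
            + self.frac_combination_at_index + self.frac_fdc_at_index
            + self.frac_single_fill + self.frac_few_visits
        )
        if branch_total > 1.0:
            raise ValueError("exclusion-branch fractions must sum to <= 1")
        if self.obs_start > self.obs_end:
            raise ValueError("obs_start must not be after obs_end")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        kwargs = dict(data)
        for key in ("obs_start", "obs_end"):
            if key in kwargs and not isinstance(kwargs[key], _dt.date):
                kwargs[key] = parse_claim_date(str(kwargs[key]))
        if "supply_days_distribution" in kwargs:
            kwargs["supply_days_distribution"] = {
                int(k): float(v) for k, v in kwargs["supply_days_distribution"].items()
            }
        for key in ("age_mean_sd", "missed_refill_delay"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# generation


def _snap_day15(dates: pd.Series) -> pd.Series:
    """Impute dates to day 15 of their month (month-resolution fields)."""
    return dates.dt.to_period("M").dt.to_timestamp() + pd.Timedelta(days=14)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


TRUTH_COLUMNS = (
    "patient_id", "initiator", "branch", "supply_days", "age_years", "sex_male",
    "calendar_year_2018", "hypertension", "dyslipidemia", "depression", "obesity",
    "hyperuricemia", "nephropathy", "linear_predictor", "true_nonpersistent",
    "true_mode", "true_discontinuation_day", "true_restarter",
)


def generate(config: SimulationConfig) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle plus its ground-truth table.

    Deterministic for a fixed ``(seed, config)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start = pd.Timestamp(config.obs_start)
    end = pd.Timestamp(config.obs_end)

    if n == 0:
        empty_truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        bundle = ClaimsBundle(
            pd.DataFrame(columns=["patient_id", "birth_ym", "sex", "obs_start", "obs_end"]),
            pd.DataFrame(columns=["patient_id", "rx_date", "atc_code", "days_supply", "fdc_flag"]),
            pd.DataFrame(columns=["patient_id", "dx_date", "icd10_code", "suspected_flag"]),
            pd.DataFrame(columns=["patient_id", "visit_date"]),
        )
        return bundle, empty_truth

    pre_days, post_days = 180, 365
    pids = np.array([f"S{i:06d}" for i in range(n)])
    male = rng.random(n) < config.male_frac
    age = np.clip(rng.normal(*config.age_mean_sd, size=n), 20.5, 73.9)
    initiator = rng.random(n) < config.frac_new_users
    n_init = int(initiator.sum())

    # index dates: both calendar years represented, windows inside observation
    lo = max(start + pd.Timedelta(days=pre_days), pd.Timestamp(2018, 1, 1))
    hi = end - pd.Timedelta(days=post_days - 1)
    lo_off = (lo - start).days
    hi_off = (hi - start).days
    index_off = np.full(n, -1, dtype=np.int64)
    index_off[initiator] = rng.integers(lo_off, hi_off + 1, size=n_init)

    branch = np.full(n, "non_user", dtype=object)
    branch_probs = [
        config.frac_prior_antidiabetic, config.frac_short_enrollment,
        config.frac_combination_at_index, config.frac_fdc_at_index,
        config.frac_single_fill, config.frac_few_visits,
    ]
    branch[initiator] = rng.choice(
        BRANCHES, size=n_init, p=[1.0 - sum(branch_probs), *branch_probs]
    )

    # planted covariates (ascertainable pre-index for initiators)
    comorbid = {
        name: rng.random(n) < prev
        for name, prev in config.comorbidity_prevalence.items()
    }
    concomitant = {
        name: rng.random(n) < prev
        for name, prev in config.concomitant_prevalence.items()
    }
    extra_dx = {
        code: rng.random(n) < prev
        for code, prev in config.extra_charlson_prevalence.items()
    }

    index_dates = start + pd.to_timedelta(np.where(initiator, index_off, 0), unit="D")
    cal2018 = pd.Series(index_dates).dt.year.to_numpy() == 2018

    centers = {
        "age_years": config.age_mean_sd[0],
        "sex_male": config.male_frac,
        "calendar_year_2018": float(np.mean(cal2018[initiator])) if n_init else 0.5,
        **config.comorbidity_prevalence,
    }
    values = {
        "age_years": age.astype(float),
        "sex_male": male.astype(float),
        "calendar_year_2018": cal2018.astype(float),
        **{k: v.astype(float) for k, v in comorbid.items()},
    }
    lp = np.zeros(n)
    for name, beta in config.covariate_log_odds.items():
        if name not in values:
            raise ValueError(f"no such plantable covariate: {name!r}")
        lp += beta * (values[name] - centers[name])

    h = config.discontinuation_hazard
    p0 = 1.0 - (1.0 - h) ** post_days if h > 0 else 0.0
    if 0.0 < p0 < 1.0:
        p_event = _expit(_logit(p0) + lp)
    else:
        p_event = np.full(n, p0)
    nonpersistent = (rng.random(n) < p_event) & initiator
    switch_mode = nonpersistent & (rng.random(n) < config.switch_to_combination_prob)
    gap_mode = nonpersistent & ~switch_mode

    # stop day for gap-mode patients: truncated geometric over the span where
    # a trailing 90-day gap is still observable before day 365
    t_max = post_days - 90 - 5
    if h > 0:
        cdf_max = 1.0 - (1.0 - h) ** t_max
        u = rng.random(n) * cdf_max
        stop_day = np.ceil(np.log1p(-u) / np.log(1.0 - h)).astype(np.int64)
        stop_day = np.clip(stop_day, 1, t_max)
    else:
        stop_day = np.full(n, t_max, dtype=np.int64)
    restarter = gap_mode & (rng.random(n) < config.restart_prob)
    switch_day = rng.integers(21, 331, size=n)

    supplies = np.array(list(config.supply_days_distribution))
    supply = rng.choice(
        supplies, size=n, p=list(config.supply_days_distribution.values())
    ).astype(np.int64)

    # ---- refill schedules for initiators ------------------------------
    init_idx = np.nonzero(initiator)[0]
    s_i = supply[init_idx]
    lower = np.maximum(1, s_i - 5)
    max_fills = int(post_days // max(1, int(lower.min()))) + 2 if n_init else 0
    # refills are on time or early (half-normal jitter, overlaps exercised);
    # an occasional missed refill adds a delay that can breach a 30-day gap
    # but, by the supply cap at 90 days, never a 90-day one
    jitter = -np.abs(rng.normal(0.0, config.refill_jitter_sd, size=(n_init, max_fills)))
    delayed = rng.random((n_init, max_fills)) < config.missed_refill_prob
    delay = rng.integers(
        config.missed_refill_delay[0], config.missed_refill_delay[1] + 1,
        size=(n_init, max_fills),
    )
    intervals = np.rint(np.where(delayed, s_i[:, None] + delay, s_i[:, None] + jitter))
    intervals = np.clip(intervals, lower[:, None], 90).astype(np.int64)
    fill_days = np.concatenate(
        [np.zeros((n_init, 1), dtype=np.int64), np.cumsum(intervals, axis=1)], axis=1
    )

    limit = np.full(n_init, post_days - 1, dtype=np.int64)
    b_i = branch[init_idx]
    limit[gap_mode[init_idx]] = stop_day[init_idx][gap_mode[init_idx]]
    limit[b_i == "single_fill"] = 0
    limit = np.where(b_i == "short_enrollment", np.minimum(limit, 170), limit)
    keep = fill_days <= limit[:, None]
    last_fill = np.where(keep, fill_days, -1).max(axis=1)

    rx_pid: list[np.ndarray] = []
    rx_day: list[np.ndarray] = []
    rx_code: list[np.ndarray] = []
    rx_supply: list[np.ndarray] = []
    rx_fdc: list[np.ndarray] = []

    rows, cols = np.nonzero(keep)
    rx_pid.append(pids[init_idx][rows])
    rx_day.append(index_off[init_idx][rows] + fill_days[rows, cols])
    is_fdc_first = (b_i[rows] == "fdc_at_index") & (cols == 0)
    rx_code.append(np.where(is_fdc_first, SGLT2I_FDC_CODE, SGLT2I_CODE))
    rx_supply.append(s_i[rows])
    rx_fdc.append(is_fdc_first)

    # restart fills after the trailing gap (branches that must keep a single
    # fill or a short enrollment window are left alone)
    re_mask = (
        restarter[init_idx]
        & (last_fill + 91 <= post_days - 1)
        & ~np.isin(b_i, ("short_enrollment", "single_fill"))
    )
    if re_mask.any():
        re_last = last_fill[re_mask]
        re_day = rng.integers(re_last + 91, post_days)
        rx_pid.append(pids[init_idx][re_mask])
        rx_day.append(index_off[init_idx][re_mask] + re_day)
        rx_code.append(np.full(int(re_mask.sum()), SGLT2I_CODE))
        rx_supply.append(s_i[re_mask])
        rx_fdc.append(np.zeros(int(re_mask.sum()), dtype=bool))
    restarter = np.zeros(n, dtype=bool)
    restarter[init_idx] = re_mask

    # switch-mode: another antidiabetic starts mid-follow-up
    sw = switch_mode[init_idx] & (b_i != "short_enrollment")
    if sw.any():
        rx_pid.append(pids[init_idx][sw])
        rx_day.append(index_off[init_idx][sw] + switch_day[init_idx][sw])
        rx_code.append(np.full(int(sw.sum()), SULFONYLUREA_CODE))
        rx_supply.append(supply[init_idx][sw])
        rx_fdc.append(np.zeros(int(sw.sum()), dtype=bool))

    # prior-user branch: an antidiabetic fill inside the washout window
    pr = b_i == "prior_antidiabetic"
    if pr.any():
        rx_pid.append(pids[init_idx][pr])
        rx_day.append(index_off[init_idx][pr] - rng.integers(20, 161, size=int(pr.sum())))
        rx_code.append(np.full(int(pr.sum()), METFORMIN_CODE))
        rx_supply.append(np.full(int(pr.sum()), 30, dtype=np.int64))
        rx_fdc.append(np.zeros(int(pr.sum()), dtype=bool))

    # combination-at-index branch: second agent on day 0
    cb = b_i == "combination_at_index"
    if cb.any():
        rx_pid.append(pids[init_idx][cb])
        rx_day.append(index_off[init_idx][cb])
        rx_code.append(np.full(int(cb.sum()), METFORMIN_CODE))
        rx_supply.append(supply[init_idx][cb])
        rx_fdc.append(np.zeros(int(cb.sum()), dtype=bool))

    # concomitant cardiometabolic prescriptions in the pre-index window
    for name, flags in concomitant.items():
        cm = flags[init_idx]
        if cm.any():
            rx_pid.append(pids[init_idx][cm])
            rx_day.append(
                index_off[init_idx][cm] - rng.integers(20, 161, size=int(cm.sum()))
            )
            rx_code.append(np.full(int(cm.sum()), CONCOMITANT_CODES[name]))
            rx_supply.append(np.full(int(cm.sum()), 30, dtype=np.int64))
            rx_fdc.append(np.zeros(int(cm.sum()), dtype=bool))

    prescriptions = pd.DataFrame(
        {
            "patient_id": np.concatenate(rx_pid) if rx_pid else np.array([], dtype=object),
            "rx_date": start + pd.to_timedelta(np.concatenate(rx_day), unit="D"),
            "atc_code": np.concatenate(rx_code),
            "days_supply": np.concatenate(rx_supply),
            "fdc_flag": np.concatenate(rx_fdc),
        }
    )

    # ---- diagnoses -----------------------------------------------------
    dx_pid: list[np.ndarray] = []
    dx_day: list[np.ndarray] = []
    dx_code: list[np.ndarray] = []
    dx_susp: list[np.ndarray] = []

    def _pre_index_days(mask_init: np.ndarray) -> np.ndarray:
        k = int(mask_init.sum())
        return index_off[init_idx][mask_init] - rng.integers(20, 161, size=k)

    all_init = np.ones(n_init, dtype=bool)
    dx_pid.append(pids[init_idx])
    dx_day.append(_pre_index_days(all_init))
    dx_code.append(np.full(n_init, "E11"))
    dx_susp.append(np.zeros(n_init, dtype=bool))

    for name, flags in comorbid.items():
        cm = flags[init_idx]
        if cm.any():
            dx_pid.append(pids[init_idx][cm])
            dx_day.append(_pre_index_days(cm))
            dx_code.append(np.full(int(cm.sum()), COMORBIDITY_DX_CODES[name]))
            dx_susp.append(np.zeros(int(cm.sum()), dtype=bool))
    for code, flags in extra_dx.items():
        cm = flags[init_idx]
        if cm.any():
            dx_pid.append(pids[init_idx][cm])
            dx_day.append(_pre_index_days(cm))
            dx_code.append(np.full(int(cm.sum()), code))
            dx_susp.append(np.zeros(int(cm.sum()), dtype=bool))
    # suspected (tentative) diagnoses that must not count
    susp = rng.random(n_init) < config.suspected_noise_prob
    if susp.any():
        codes = rng.choice(list(COMORBIDITY_DX_CODES.values()), size=int(susp.sum()))
        dx_pid.append(pids[init_idx][susp])
        dx_day.append(_pre_index_days(susp))
        dx_code.append(codes)
        dx_susp.append(np.ones(int(susp.sum()), dtype=bool))

    # non-initiators: diabetes code somewhere in the window
    non_idx = np.nonzero(~initiator)[0]
    if non_idx.size:
        span = (end - start).days - 30
        dx_pid.append(pids[non_idx])
        dx_day.append(rng.integers(15, span, size=non_idx.size))
        dx_code.append(np.full(non_idx.size, "E11"))
        dx_susp.append(np.zeros(non_idx.size, dtype=bool))

    dx_dates = _snap_day15(
        pd.Series(start + pd.to_timedelta(np.concatenate(dx_day), unit="D"))
    )
    diagnoses = pd.DataFrame(
        {
            "patient_id": np.concatenate(dx_pid),
            "dx_date": dx_dates,
            "icd10_code": np.concatenate(dx_code),
            "suspected_flag": np.concatenate(dx_susp),
        }
    )

    # ---- visits --------------------------------------------------------
    vis_pid: list[np.ndarray] = []
    vis_day: list[np.ndarray] = []
    n_pre_visits = np.maximum(rng.poisson(config.visit_rate_mean, size=n_init), 2)
    n_pre_visits[b_i == "few_visits"] = 1
    reps = n_pre_visits
    vis_pid.append(np.repeat(pids[init_idx], reps))
    vis_day.append(
        np.repeat(index_off[init_idx], reps) - rng.integers(20, 161, size=int(reps.sum()))
    )
    # a visit accompanies each fill early enough to stay inside enrollment
    fill_visit = keep & (fill_days <= 330)
    rows, cols = np.nonzero(fill_visit)
    vis_pid.append(pids[init_idx][rows])
    vis_day.append(index_off[init_idx][rows] + fill_days[rows, cols])
    if non_idx.size:
        nv = rng.integers(2, 7, size=non_idx.size)
        span = (end - start).days - 30
        vis_pid.append(np.repeat(pids[non_idx], nv))
        vis_day.append(rng.integers(15, span, size=int(nv.sum())))

    visit_dates = _snap_day15(
        pd.Series(start + pd.to_timedelta(np.concatenate(vis_day), unit="D"))
    )
    visits = pd.DataFrame(
        {"patient_id": np.concatenate(vis_pid), "visit_date": visit_dates}
    )

    # ---- enrollment ----------------------------------------------------
    age_anchor = pd.Series(np.where(initiator, index_dates, start))
    birth = pd.to_datetime(age_anchor) - pd.to_timedelta(
        np.rint(age * 365.25).astype(np.int64), unit="D"
    )
    # non-initiators must stay under 75 through the whole window
    non_young = pd.to_datetime(age_anchor) - pd.to_timedelta(
        np.rint(np.minimum(age, 71.5) * 365.25).astype(np.int64), unit="D"
    )
    birth = pd.Series(np.where(initiator, birth, non_young))
    birth_ym = pd.to_datetime(birth).dt.strftime("%Y%m")

    # the stored birth is month-resolution: the age-75 disenrollment cap must
    # use the day-15-imputed birthday, as a consumer of the table would
    birth_imputed = _snap_day15(pd.to_datetime(birth))
    cap = birth_imputed + pd.DateOffset(years=75) - pd.Timedelta(days=1)
    obs_end_col = pd.Series(np.minimum(np.repeat(end.to_datetime64(), n), cap.to_numpy()))
    short = branch == "short_enrollment"
    short_end = pd.to_datetime(pd.Series(index_dates)) + pd.Timedelta(days=200)
    obs_end_col = pd.Series(np.where(short, short_end, obs_end_col))

    enrollment = pd.DataFrame(
        {
            "patient_id": pids,
            "birth_ym": birth_ym.to_numpy(),
            "sex": np.where(male, "male", "female"),
            "obs_start": np.repeat(start.to_datetime64(), n),
            "obs_end": pd.to_datetime(obs_end_col).to_numpy(),
        }
    )

    # ---- truth ---------------------------------------------------------
    event_day = np.full(n, np.nan)
    gap_idx = init_idx[gap_mode[init_idx]]
    gm = gap_mode[init_idx]
    event_day[gap_idx] = np.minimum(last_fill[gm] + s_i[gm], post_days)
    swi = init_idx[switch_mode[init_idx]]
    event_day[swi] = switch_day[swi]
    mode = np.where(switch_mode, "switch", np.where(gap_mode, "gap", "none"))
    mode = np.where(initiator, mode, "none")

    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "initiator": initiator,
            "branch": branch,
            "supply_days": supply,
            "age_years": age,
            "sex_male": male,
            "calendar_year_2018": np.where(initiator, cal2018, False),
            **{k: v for k, v in comorbid.items()},
            "linear_predictor": lp,
            "true_nonpersistent": nonpersistent,
            "true_mode": mode,
            "true_discontinuation_day": event_day,
            "true_restarter": restarter,
        }
    )

    bundle = ClaimsBundle(enrollment, prescriptions, diagnoses, visits)
    return bundle, truth


# ---------------------------------------------------------------------------
# hand-authored worked fixture


def _d(raw: str) -> pd.Timestamp:
    return pd.Timestamp(parse_claim_date(raw))


#: expected cohort outcome per worked-fixture patient
WORKED_EXPECTED_BRANCH = {
    "P01": "included",
    "P02": "included",
    "P03": "included",
    "P04": "included",
    "P05": "included",
    "P06": "included",
    "P07": "prior_antidiabetic",
    "P08": "insufficient_enrollment",
    "P09": "combination_at_index",
    "P10": "fdc_at_index",
    "P11": "single_sglt2i_rx",
    "P12": "lt2_pre_visits",
}

#: expected exposure under the 90-day gap policy:
#: patient -> (persistence_days, discontinued, reason, restarted, covered_days)
WORKED_EXPECTED_EXPOSURE = {
    "P01": (365, False, "none", False, 365),
    "P02": (30, True, "gap", True, 60),
    "P03": (365, False, "none", False, 315),
    "P04": (40, True, "switch", False, 365),
    "P05": (150, True, "gap", False, 150),
    "P06": (365, False, "none", False, 305),
}

#: expected persistence_days under the 30-day sensitivity policy
WORKED_EXPECTED_PERSISTENCE_30 = {
    "P01": 365,
    "P02": 30,
    "P03": 30,
    "P04": 40,
    "P05": 150,
    "P06": 30,
}


def make_worked_fixture() -> ClaimsBundle:
    """Small hand-authored population covering every cohort-exclusion branch
    and every persistence/adherence branch.

    Twelve patients share the index date 2018-07-16 (where applicable):
    six are included (clean persistence; >90-day gap with restart; a gap in
    (30, 90] that only the sensitivity policy flags; switch to combination
    therapy; trailing gap without restart; an exactly-90-day boundary gap)
    and six exercise one exclusion branch each.
    """
    index = "20180716"
    full_obs = ("201709", "202010")

    enrollment_rows = []
    rx_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    visit_rows: list[tuple] = []

    def patient(pid: str, *, birth="196504", sex="male", obs=full_obs,
                pre_visits=("201803", "201805")) -> None:
        enrollment_rows.append((pid, birth, sex, _d(obs[0]), _d(obs[1])))
        for v in pre_visits:
            visit_rows.append((pid, _d(v)))
        dx_rows.append((pid, _d("201804"), "E11", False))

    def fills(pid: str, day_offsets, supply=30, code=SGLT2I_CODE, fdc=False) -> None:
        for off in day_offsets:
            rx_rows.append(
                (pid, _d(index) + pd.Timedelta(days=int(off)), code, supply, fdc)
            )

    monthly = list(range(0, 361, 30))

    patient("P01")                      # clean persistence, full coverage
    fills("P01", monthly)
    dx_rows += [
        ("P01", _d("201804"), "I10", False),
        ("P01", _d("201805"), "E785", False),
        ("P01", _d("201806"), "E790", False),
    ]
    rx_rows += [
        ("P01", _d("201804"), "C09AA02", 30, False),
        ("P01", _d("201805"), "C10AA07", 30, False),
    ]

    patient("P02", sex="female")        # >90-day gap, then a restart fill
    fills("P02", [0, 100])
    dx_rows.append(("P02", _d("201805"), "E785", True))  # suspected only

    patient("P03")                      # gap of 80 days: sensitivity-only event
    fills("P03", [0] + list(range(80, 351, 30)))
    dx_rows.append(("P03", _d("201804"), "E112", False))

    patient("P04")                      # switch to combination therapy at day 40
    fills("P04", monthly)
    rx_rows.append(("P04", _d(index) + pd.Timedelta(days=40), SULFONYLUREA_CODE, 30, False))

    patient("P05", sex="female")        # trailing gap, no restart
    fills("P05", [0, 30, 60, 90, 120])

    patient("P06")                      # boundary: gap of exactly 90 days is tolerated
    fills("P06", [0] + list(range(90, 361, 30)))

    patient("P07")                      # prior antidiabetic inside washout
    fills("P07", monthly)
    rx_rows.append(("P07", _d("20180417"), METFORMIN_CODE, 30, False))

    patient("P08", obs=("201709", "20190201"))  # enrollment ends 200 days post-index
    fills("P08", [0, 30, 60, 90, 120, 150])

    patient("P09")                      # combination therapy at the index date
    fills("P09", monthly)
    rx_rows.append(("P09", _d(index), METFORMIN_CODE, 30, False))

    patient("P10")                      # fixed-dose combination product at index
    fills("P10", [0], code=SGLT2I_FDC_CODE, fdc=True)
    fills("P10", monthly[1:])

    patient("P11")                      # only one SGLT2i prescription
    fills("P11", [0])

    patient("P12", pre_visits=("201805",))  # a single pre-index visit
    fills("P12", monthly)

    bundle = ClaimsBundle(
        pd.DataFrame(
            enrollment_rows,
            columns=["patient_id", "birth_ym", "sex", "obs_start", "obs_end"],
        ),
        pd.DataFrame(
            rx_rows,
            columns=["patient_id", "rx_date", "atc_code", "days_supply", "fdc_flag"],
        ),
        pd.DataFrame(
            dx_rows, columns=["patient_id", "dx_date", "icd10_code", "suspected_flag"]
        ),
        pd.DataFrame(visit_rows, columns=["patient_id", "visit_date"]),
    )
    return bundle.validate()
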