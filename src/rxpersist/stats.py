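"""Statistical layer: Kaplan–Meier persistence, person-year incidence,
crude/adjusted logistic odds ratios, multicollinearity screening and simple
linear regressions.

Conventions: outcomes are coded 1 = non-persistent (or 1 = poor adherent),
continuous covariates enter linearly, odds ratios are exponentiated
maximum-likelihood coefficients with Wald 95% confidence intervals, and the
crude odds ratio for a covariate is the single-covariate logistic fit (for
a binary covariate this equals the 2x2 cross-product ratio).  Patients
persisting past the end of follow-up are censored there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "KMCurve",
    "IncidenceResult",
    "LinearFit",
    "km_estimate",
    "incidence",
    "fit_logistic",
    "fit_or_table",
    "check_multicollinearity",
    "fit_linear",
]


@dataclass
class KMCurve:
    """Product-limit estimate on the day grid of observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


@dataclass
class IncidenceResult:
    events: int
    person_years: float
    rate_per_1000py: float


@dataclass
class LinearFit:
    slope: float
    ci_lower: float
    ci_upper: float
    p_value: float
    intercept: float


def km_estimate(times, events, *, followup_days: int = 365) -> KMCurve:
    """Kaplan–Meier survival of persistence times.

    ``times`` are persistence days in ``[0, followup_days]``; ``events``
    flags discontinuation (censored patients carry ``followup_days``).
    Same-day ties are processed together, as in the product-limit formula
    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one observation")
    if times.min() < 0 or times.max() > followup_days:
        raise ValueError(f"persistence times must lie in [0, {followup_days}]")

    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    table = fitter.event_table
    event_rows = table[table["observed"] > 0]
    surv = fitter.survival_function_["KM_estimate"]
    ci = fitter.confidence_interval_survival_function_
    t = event_rows.index.to_numpy(dtype=float)
    return KMCurve(
        event_times=t,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
        survival=surv.loc[event_rows.index].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].loc[event_rows.index].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].loc[event_rows.index].to_numpy(dtype=float),
    )


def incidence(exposure: pd.DataFrame, *, followup_days: int = 365) -> IncidenceResult:
    """Events per 1000 person-years from per-patient persistence results."""
    events = int(exposure["discontinued"].sum())
    person_years = float(exposure["persistence_days"].sum()) / 365.0
    if person_years <= 0:
        raise ValueError("zero person-years of follow-up")
    return IncidenceResult(events, person_years, 1000.0 * events / person_years)


def _fit_one_logistic(y: np.ndarray, X: pd.DataFrame):
    """Logit MLE; returns (result, note). A failed fit yields (None, why)."""
    design = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # separation, singular design, ...
            return None, f"fit failed: {type(exc).__name__}"
    if not res.mle_retvals.get("converged", True):
        return None, "did not converge"
    return res, ""


def fit_logistic(
    outcome, covariates: pd.DataFrame, mode: str = "adjusted"
) -> pd.DataFrame:
    """Odds ratios with Wald 95% CIs for one outcome.

    ``mode='crude'`` fits one single-covariate model per column;
    ``mode='adjusted'`` fits all columns jointly.  Returns a frame indexed by
    covariate with ``or_``, ``ci_lower``, ``ci_upper``, ``p_value`` and a
    ``note`` column naming any per-covariate fit failure (never raising).
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must include both classes")
    rows = {}
    if mode == "crude":
        fits = {name: _fit_one_logistic(y, covariates[[name]]) for name in covariates}
    elif mode == "adjusted":
        joint = _fit_one_logistic(y, covariates)
        fits = {name: joint for name in covariates}
    else:
        raise ValueError("mode must be 'crude' or 'adjusted'")
    for name, (res, note) in fits.items():
        if res is None or name not in res.params.index:
            rows[name] = (np.nan, np.nan, np.nan, np.nan, note or "missing term")
            continue
        lo, hi = res.conf_int().loc[name]
        rows[name] = (
            float(np.exp(res.params[name])),
            float(np.exp(lo)),
            float(np.exp(hi)),
            float(res.pvalues[name]),
            "",
        )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["or_", "ci_lower", "ci_upper", "p_value", "note"]
    )
    out.index.name = "covariate"
    return out


def fit_or_table(outcome, covariates: pd.DataFrame, outcome_label: str = "") -> pd.DataFrame:
    """Crude and adjusted odds ratios side by side for every covariate."""
    crude = fit_logistic(outcome, covariates, mode="crude")
    adjusted = fit_logistic(outcome, covariates, mode="adjusted")
    table = pd.DataFrame(
        {
            "crude_or": crude["or_"],
            "crude_ci_lower": crude["ci_lower"],
            "crude_ci_upper": crude["ci_upper"],
            "crude_p": crude["p_value"],
            "adjusted_or": adjusted["or_"],
            "adjusted_ci_lower": adjusted["ci_lower"],
            "adjusted_ci_upper": adjusted["ci_upper"],
            "adjusted_p": adjusted["p_value"],
            "note": (crude["note"] + " " + adjusted["note"]).str.strip(),
        }
    )
    table.attrs["outcome_label"] = outcome_label
    table.attrs["n_outcome"] = int(np.asarray(outcome).sum())
    table.attrs["n_reference"] = int(len(outcome) - np.asarray(outcome).sum())
    return table


def check_multicollinearity(
    covariates: pd.DataFrame, *, threshold: float = 10.0
) -> pd.DataFrame:
    """Variance inflation factor per covariate of the adjusted design.

    Constant (zero-variance) columns are reported as degenerate with an
    undefined VIF rather than raising.
    """
    X = covariates.astype(float)
    rows = []
    constant = X.nunique() <= 1
    design = sm.add_constant(X.loc[:, ~constant], has_constant="add")
    positions = {name: i for i, name in enumerate(design.columns)}
    for name in X.columns:
        if constant[name]:
            rows.append((name, np.nan, True, "degenerate: constant column"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vif = variance_inflation_factor(design.to_numpy(), positions[name])
        note = "unbounded: perfect collinearity" if not np.isfinite(vif) else ""
        rows.append((name, float(vif), bool(not np.isfinite(vif) or vif > threshold), note))
    return pd.DataFrame(rows, columns=["covariate", "vif", "flagged", "note"])


def fit_linear(response, predictor) -> LinearFit:
    """Ordinary least squares of a response on a single predictor."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    lo, hi = res.conf_int()[1]
    return LinearFit(
        slope=float(res.params[1]),
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=float(res.pvalues[1]),
        intercept=float(res.params[0]),
    )
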