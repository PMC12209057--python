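"""Statistical layer: KM, incidence, logistic ORs, VIF, linear fits."""

import numpy as np
import pandas as pd
import pytest

from rxpersist.stats import (
    check_multicollinearity,
    fit_linear,
    fit_logistic,
    fit_or_table,
    incidence,
    km_estimate,
)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """(1 - 2/5) = 0.6 after day 100; x (1 - 1/3) = 0.4 after day 200."""
        times = [100, 100, 200, 365, 365]
        events = [True, True, True, False, False]
        km = km_estimate(times, events)
        assert km.survival_at(100) == pytest.approx(0.6)
        assert km.survival_at(200) == pytest.approx(0.4)
        assert km.survival_at(365) == pytest.approx(0.4)
        assert km.survival_at(50) == 1.0

    def test_no_events_survival_stays_one(self):
        km = km_estimate([365] * 10, [False] * 10)
        assert km.survival_at(365) == 1.0

    def test_all_events_day_one(self):
        km = km_estimate([1, 1, 1], [True] * 3)
        assert km.survival_at(1) == 0.0
        assert km.survival_at(300) == 0.0

    def test_survival_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        times = rng.integers(1, 366, size=500)
        events = rng.random(500) < 0.6
        times[~events] = 365
        km = km_estimate(times, events)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival.min() >= 0 and km.survival.max() <= 1
        assert (np.diff(km.at_risk) <= 0).all()

    def test_equals_empirical_without_interior_censoring(self):
        """With all censoring at day 365 the KM curve is the empirical
        survival function of the event times."""
        rng = np.random.default_rng(8)
        times = rng.integers(1, 300, size=2000)
        events = np.ones(2000, dtype=bool)
        km = km_estimate(times, events)
        for t in (50, 100, 200, 299):
            empirical = (times > t).mean()
            assert km.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([400], [True])


class TestIncidence:
    def test_rate_arithmetic(self):
        exp = pd.DataFrame(
            {"discontinued": [True] * 10 + [False] * 10,
             "persistence_days": [365 * 25.0] * 20}
        )
        assert incidence(exp).rate_per_1000py == pytest.approx(20.0)

    def test_zero_events(self):
        exp = pd.DataFrame({"discontinued": [False] * 5, "persistence_days": [365] * 5})
        assert incidence(exp).rate_per_1000py == 0.0

    def test_zero_person_years_raises(self):
        exp = pd.DataFrame({"discontinued": [True], "persistence_days": [0]})
        with pytest.raises(ValueError):
            incidence(exp)


class TestLogistic:
    def test_crude_or_matches_2x2_closed_form(self):
        """(20 x 90) / (80 x 10) = 2.25 from the cross-product ratio."""
        y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
        x = pd.DataFrame({"exposed": np.r_[np.ones(100), np.zeros(100)]})
        out = fit_logistic(y, x, mode="crude")
        assert out.loc["exposed", "or_"] == pytest.approx(2.25, rel=1e-6)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(0)
        n = 10000
        y = rng.random(n) < 0.5
        x = pd.DataFrame({"noise": rng.random(n) < 0.5})
        out = fit_logistic(y.astype(int), x, mode="crude")
        assert 0.9 < out.loc["noise", "or_"] < 1.1

    def test_adjusted_conditions_on_confounder(self):
        rng = np.random.default_rng(1)
        n = 20000
        confounder = rng.random(n) < 0.5
        exposure = rng.random(n) < np.where(confounder, 0.7, 0.3)
        p = 1 / (1 + np.exp(-(-1.0 + 1.2 * confounder)))  # exposure has no effect
        y = (rng.random(n) < p).astype(int)
        X = pd.DataFrame({"exposure": exposure, "confounder": confounder})
        crude = fit_logistic(y, X[["exposure"]], mode="crude")
        adjusted = fit_logistic(y, X, mode="adjusted")
        assert crude.loc["exposure", "or_"] > 1.15  # confounded upward
        assert 0.9 < adjusted.loc["exposure", "or_"] < 1.1

    def test_separation_reported_not_raised(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = pd.DataFrame({"perfect": y.astype(bool)})
        out = fit_logistic(y, x, mode="crude")
        row = out.loc["perfect"]
        assert np.isnan(row["or_"]) or row["note"]

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10)}))

    def test_or_table_carries_counts(self):
        rng = np.random.default_rng(2)
        y = (rng.random(500) < 0.4).astype(int)
        X = pd.DataFrame({"a": rng.random(500) < 0.5, "b": rng.normal(size=500)})
        table = fit_or_table(y, X, "non-persistence")
        assert table.attrs["n_outcome"] + table.attrs["n_reference"] == 500
        assert {"crude_or", "adjusted_or"} <= set(table.columns)


class TestVIF:
    def test_independent_covariates_near_one(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc"))
        out = check_multicollinearity(X)
        assert (out["vif"] < 1.1).all()
        assert not out["flagged"].any()

    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=500)
        X = pd.DataFrame({"a": a, "b": a})
        out = check_multicollinearity(X).set_index("covariate")
        assert out.loc["a", "flagged"] and out.loc["b", "flagged"]

    def test_vif_tracks_r_squared(self):
        """x2 = x1 + noise with R^2 ~= 0.99 gives VIF ~= 1/(1-R^2) ~= 100."""
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=20000)
        x2 = x1 + rng.normal(scale=0.1, size=20000)
        out = check_multicollinearity(pd.DataFrame({"x1": x1, "x2": x2}))
        assert out["vif"].between(80, 125).all()

    def test_constant_column_degenerate(self):
        X = pd.DataFrame({"c": np.ones(100), "x": np.arange(100.0)})
        out = check_multicollinearity(X).set_index("covariate")
        assert np.isnan(out.loc["c", "vif"])
        assert "degenerate" in out.loc["c", "note"]


class TestLinear:
    def test_exact_line(self):
        x = np.arange(50.0)
        fit = fit_linear(2 * x, x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.ci_upper - fit.ci_lower == pytest.approx(0.0, abs=1e-8)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=1000)
        y = 0.5 * x + rng.normal(size=1000)
        fit = fit_linear(y, x)
        assert fit.ci_lower <= 0.5 <= fit.ci_upper

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(10)
        fit = fit_linear(rng.normal(size=1000), rng.normal(size=1000))
        assert fit.ci_lower <= 0.0 <= fit.ci_upper

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError):
            fit_linear(np.arange(10.0), np.ones(10))
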