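"""Exposure engine: coverage union, gap/switch/restart rules, PDC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rxpersist as rp
from rxpersist.exposure import GapPolicy, covered_days, detect_discontinuation, detect_restart
from rxpersist.synthetic import (
    WORKED_EXPECTED_EXPOSURE,
    WORKED_EXPECTED_PERSISTENCE_30,
)

from conftest import brute_force_covered_days


class TestCoveredDays:
    @pytest.mark.parametrize(
        "fills, supplies, expected",
        [
            ([0], [365], 365),          # single fill covering the whole window
            ([0, 20], [30, 30], 50),    # overlap counted once: [0,30) u [20,50)
            ([350], [30], 15),          # clipped at day 365
            ([0, 30], [30, 30], 60),    # contiguous
            ([], [], 0),
        ],
    )
    def test_examples(self, fills, supplies, expected):
        assert covered_days(np.array(fills), np.array(supplies)) == expected

    def test_out_of_window_fill_warns_not_raises(self):
        with pytest.warns(UserWarning, match="ignored"):
            assert covered_days(np.array([-10, 0]), np.array([30, 30])) == 30

    @given(
        st.lists(
            st.tuples(st.integers(0, 364), st.integers(1, 90)),
            min_size=0,
            max_size=25,
        )
    )
    def test_matches_boolean_array_oracle(self, fills):
        days = np.array([f[0] for f in fills])
        supplies = np.array([f[1] for f in fills])
        assert covered_days(days, supplies, _warn=False) == brute_force_covered_days(
            days, supplies
        )

    def test_bounded_by_total_supply(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = rng.integers(1, 15)
            days = np.sort(rng.integers(0, 365, size=k))
            supplies = rng.integers(1, 91, size=k)
            got = covered_days(days, supplies, _warn=False)
            assert got <= min(365, int(supplies.sum()))


class TestDetectDiscontinuation:
    def test_gap_event_dated_at_supply_runout(self):
        # fills at day 0 and 100 with 30-day supplies: gap 100 > 90
        p, d, reason = detect_discontinuation([0, 100], [30, 30], [])
        assert (p, d, reason) == (30, True, "gap")

    def test_monthly_refills_persist(self):
        days = list(range(0, 331, 30))
        p, d, reason = detect_discontinuation(days, [30] * len(days), [])
        assert (p, d, reason) == (365, False, "none")

    def test_switch_event_at_other_agent_fill(self):
        p, d, reason = detect_discontinuation([0, 30, 60], [30] * 3, [40])
        assert (p, d, reason) == (40, True, "switch")

    def test_boundary_gap_of_exactly_90_tolerated(self):
        days = [0] + list(range(90, 361, 30))
        p, d, reason = detect_discontinuation(days, [30] * len(days), [])
        assert (p, d, reason) == (365, False, "none")

    def test_trailing_gap(self):
        p, d, reason = detect_discontinuation([0, 30, 60, 90, 120], [30] * 5, [])
        assert (p, d, reason) == (150, True, "gap")

    def test_earliest_event_wins(self):
        # switch at day 20 precedes the later gap event
        p, d, reason = detect_discontinuation([0, 200], [30, 30], [20])
        assert (p, d, reason) == (20, True, "switch")

    def test_empty_fill_list_is_contract_error(self):
        with pytest.raises(ValueError, match="no index-drug fill"):
            detect_discontinuation([], [], [])

    def test_30_day_policy_flags_midsize_gap(self):
        days = [0] + list(range(80, 351, 30))
        p90 = detect_discontinuation(days, [30] * len(days), [])
        p30 = detect_discontinuation(days, [30] * len(days), [], GapPolicy(30))
        assert p90 == (365, False, "none")
        assert p30 == (30, True, "gap")


class TestDetectRestart:
    def test_fill_after_event_counts(self):
        assert detect_restart(np.array([0, 200]), 30) is True

    def test_no_further_fill(self):
        assert detect_restart(np.array([0, 270]), 300) is False

    def test_fill_at_day_365_does_not_count(self):
        assert detect_restart(np.array([0, 365]), 30) is False

    def test_contract_error_without_event(self):
        with pytest.raises(ValueError):
            detect_restart(np.array([0]), None)


class TestComputeExposure:
    def test_worked_fixture_classification(self, worked_bundle, worked_cohort):
        cohort, _ = worked_cohort
        exp = rp.compute_exposure(cohort, worked_bundle, GapPolicy(90)).set_index("patient_id")
        for pid, (p, d, reason, restart, cov) in WORKED_EXPECTED_EXPOSURE.items():
            row = exp.loc[pid]
            assert (
                row["persistence_days"], row["discontinued"], row["reason"],
                row["restarted"], row["covered_days"],
            ) == (p, d, reason, restart, cov), pid

    def test_worked_fixture_sensitivity_policy(self, worked_bundle, worked_cohort):
        cohort, _ = worked_cohort
        exp = rp.compute_exposure(cohort, worked_bundle, GapPolicy(30)).set_index("patient_id")
        for pid, p in WORKED_EXPECTED_PERSISTENCE_30.items():
            assert exp.loc[pid, "persistence_days"] == p, pid

    def test_empty_cohort(self, worked_bundle, worked_cohort):
        cohort, _ = worked_cohort
        out = rp.compute_exposure(cohort.iloc[0:0], worked_bundle)
        assert out.empty

    def test_pdc_identity_and_threshold(self, synth_cohort):
        bundle, cohort, _ = synth_cohort
        exp = rp.compute_exposure(cohort, bundle)
        assert np.allclose(exp["pdc"], exp["covered_days"] / 365)
        assert (exp["adherent"] == (exp["pdc"] >= 0.80)).all()
        assert exp["restarted"].le(exp["discontinued"]).all()  # restart => event
        persistent = exp[~exp["discontinued"]]
        assert (persistent["persistence_days"] == 365).all()

    def test_gap_policy_monotone_per_patient(self, synth_cohort):
        bundle, cohort, _ = synth_cohort
        e90 = rp.compute_exposure(cohort, bundle, GapPolicy(90))
        e30 = rp.compute_exposure(cohort, bundle, GapPolicy(30))
        assert (e90["persistence_days"].to_numpy() >= e30["persistence_days"].to_numpy()).all()
        assert (1 - e90["discontinued"].mean()) >= (1 - e30["discontinued"].mean())

    def test_covered_days_oracle_on_synthetic_patients(self, synth_cohort):
        bundle, cohort, _ = synth_cohort
        exp = rp.compute_exposure(cohort, bundle).set_index("patient_id")
        rx = bundle.prescriptions.merge(
            cohort[["patient_id", "index_date"]], on="patient_id"
        )
        rx = rx[rx["atc_code"].str.startswith("A10P")]
        rx["day"] = (rx["rx_date"] - rx["index_date"]).dt.days
        count = 0
        for pid, group in rx.groupby("patient_id"):
            expected = brute_force_covered_days(
                group["day"].to_numpy(), group["days_supply"].to_numpy()
            )
            assert exp.loc[pid, "covered_days"] == expected, pid
            count += 1
            if count >= 1000:
                break
        assert count >= 1000
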