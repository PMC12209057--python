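"""Covariate derivation: comorbidity flags, drug classes, visits, Charlson."""

import numpy as np
import pandas as pd
import pytest

import rxpersist as rp
from rxpersist import cci
from rxpersist.covariates import (
    DEFAULT_CODE_MAP,
    compute_cci,
    count_concomitant_classes,
    flag_comorbidity,
    visit_stats,
)

INDEX = pd.Timestamp("2018-07-16")


def _dx(rows):
    return pd.DataFrame(rows, columns=["dx_date", "icd10_code", "suspected_flag"])


class TestFlagComorbidity:
    def test_confirmed_diagnosis_in_window(self):
        dx = _dx([(INDEX - pd.Timedelta(days=30), "I10", False)])
        assert flag_comorbidity(dx, ("I10",), INDEX) is True

    def test_suspected_diagnosis_excluded(self):
        dx = _dx([(INDEX - pd.Timedelta(days=30), "E78", True)])
        assert flag_comorbidity(dx, ("E78",), INDEX) is False

    def test_outside_window_excluded(self):
        dx = _dx([(INDEX - pd.Timedelta(days=200), "E790", False)])
        assert flag_comorbidity(dx, ("E790",), INDEX) is False

    def test_code_normalisation(self):
        dx = _dx([(INDEX - pd.Timedelta(days=30), "e78.5", False)])
        assert flag_comorbidity(dx, ("E78",), INDEX) is True


class TestConcomitantClasses:
    def _rx(self, codes, day=-30):
        return pd.DataFrame(
            {
                "rx_date": [INDEX + pd.Timedelta(days=day)] * len(codes),
                "atc_code": codes,
            }
        )

    def test_two_distinct_classes(self):
        assert count_concomitant_classes(self._rx(["C09AA02", "C10AA07"]), INDEX) == 2

    def test_repeat_fills_count_once(self):
        assert count_concomitant_classes(self._rx(["C08CA01"] * 5), INDEX) == 1

    def test_empty_window(self):
        assert count_concomitant_classes(self._rx(["C09AA02"], day=-300), INDEX) == 0

    def test_unlisted_class_ignored(self):
        assert count_concomitant_classes(self._rx(["N02BE01"]), INDEX) == 0


class TestVisitStats:
    def _vis(self, offsets):
        return pd.DataFrame(
            {"visit_date": [INDEX + pd.Timedelta(days=o) for o in offsets]}
        )

    def test_evenly_spaced(self):
        assert visit_stats(self._vis([-180, -120, -60]), INDEX) == (3, 60.0)

    def test_two_visits(self):
        assert visit_stats(self._vis([-40, -7]), INDEX) == (2, 33.0)

    def test_duplicates_collapse_for_interval_only(self):
        n, interval = visit_stats(self._vis([-60, -60, -30]), INDEX)
        assert n == 3            # every claim is a visit
        assert interval == 30.0  # interval over distinct dates

    def test_single_distinct_date(self):
        assert visit_stats(self._vis([-30, -30]), INDEX) == (2, 0.0)

    def test_contract_error_below_two(self):
        with pytest.raises(ValueError, match="< 2"):
            visit_stats(self._vis([-30]), INDEX)


class TestCharlson:
    def test_no_qualifying_diagnoses(self):
        assert cci.charlson_index([]) == 0
        assert cci.charlson_index(["I10", "E785"]) == 0  # not Charlson categories

    def test_uncomplicated_diabetes_scores_one(self):
        assert cci.charlson_index(["E11"]) == 1
        assert cci.charlson_index(["E119"]) == 1

    def test_two_weight_one_categories(self):
        assert cci.charlson_index(["E11", "B182"]) == 2  # diabetes + mild liver

    def test_hierarchy_diabetes_complication(self):
        # complicated diabetes (weight 2) supersedes uncomplicated (weight 1)
        assert cci.charlson_index(["E11", "E112"]) == 2

    def test_hierarchy_metastatic(self):
        assert cci.charlson_index(["C50", "C78"]) == 6

    def test_monotone_in_diagnoses(self):
        rng = np.random.default_rng(11)
        pool = ["E11", "E112", "I21", "I500", "J449", "K259", "B182", "K704",
                "N189", "C50", "C78", "F01", "I10", "Z999"]
        for _ in range(100):
            k = rng.integers(0, 8)
            codes = list(rng.choice(pool, size=k))
            extra = str(rng.choice(pool))
            assert cci.charlson_index(codes + [extra]) >= cci.charlson_index(codes)

    def test_compute_cci_respects_window_and_flags(self):
        dx = pd.DataFrame(
            {
                "dx_date": [INDEX - pd.Timedelta(days=30), INDEX - pd.Timedelta(days=30),
                            INDEX - pd.Timedelta(days=300)],
                "icd10_code": ["E11", "I21", "C78"],
                "suspected_flag": [False, True, False],
            }
        )
        assert compute_cci(dx, INDEX) == 1  # suspected MI and out-of-window tumour drop


class TestBuildCovariates:
    def test_worked_fixture_values(self, worked_bundle, worked_cohort):
        cohort, _ = worked_cohort
        cov = rp.build_covariates(cohort, worked_bundle).set_index("patient_id")
        p01 = cov.loc["P01"]
        assert p01[["hypertension", "dyslipidemia", "hyperuricemia"]].all()
        assert not p01[["depression", "obesity", "nephropathy"]].any()
        assert p01["n_concomitant_classes"] == 2
        assert p01["cci"] == 1
        # P02's only dyslipidemia record is a suspected diagnosis
        assert not cov.loc["P02", "dyslipidemia"]
        # P03 carries a diabetes-with-complication code
        assert cov.loc["P03", "nephropathy"]
        assert cov.loc["P03", "cci"] == 2

    def test_pre_window_only(self, worked_bundle, worked_cohort):
        """Post-index claims never influence the baseline covariates."""
        cohort, _ = worked_cohort
        before = rp.build_covariates(cohort, worked_bundle)
        bundle = worked_bundle.copy()
        extra = pd.DataFrame(
            {
                "patient_id": ["P01"],
                "dx_date": [INDEX + pd.Timedelta(days=30)],
                "icd10_code": ["C78"],
                "suspected_flag": [False],
            }
        )
        bundle.diagnoses = pd.concat([bundle.diagnoses, extra], ignore_index=True)
        after = rp.build_covariates(cohort, bundle)
        pd.testing.assert_frame_equal(before, after)

    def test_custom_code_map(self, worked_bundle, worked_cohort):
        cohort, _ = worked_cohort
        swapped = rp.CodeMap(
            comorbidities={**DEFAULT_CODE_MAP.comorbidities,
                           "hypertension": ("E78",), "dyslipidemia": ("I10",)},
        )
        cov = rp.build_covariates(cohort, worked_bundle, code_map=swapped).set_index("patient_id")
        # P01 has both I10 and E785 records, so both flags stay on either way
        assert cov.loc["P01", ["hypertension", "dyslipidemia"]].all()
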