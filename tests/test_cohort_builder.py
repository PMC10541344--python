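"""Cohort construction: CKD-EPI, eligibility flow, classification,
mediators, covariate lookbacks and follow-up derivation."""

import numpy as np
import pandas as pd
import pytest

import t2dmace as t
from t2dmace.cohort_builder import (
    ClassificationError,
    SchemaError,
    classify_exposure,
    derive_mediators,
)


class TestCkdEpi:
    @pytest.mark.parametrize(
        "scr,age,sex,expected",
        [
            # direct evaluations of the published closed form
            (0.70, 60, "F", 141 * 1.018 * 0.993**60),
            (1.20, 60, "M", 141 * (1.2 / 0.9) ** -1.209 * 0.993**60),
        ],
    )
    def test_closed_form(self, scr, age, sex, expected):
        assert t.compute_egfr_ckdepi(scr, age, sex) == pytest.approx(expected, rel=1e-12)

    def test_published_magnitudes(self):
        assert t.compute_egfr_ckdepi(0.70, 60, "F") == pytest.approx(94.2, abs=0.1)
        assert t.compute_egfr_ckdepi(1.20, 60, "M") == pytest.approx(65.3, abs=0.1)

    @pytest.mark.parametrize("sex,kappa", [("F", 0.7), ("M", 0.9)])
    def test_boundary_identity_at_kappa(self, sex, kappa):
        # Scr = kappa: both the min and max terms equal one
        female = 1.018 if sex == "F" else 1.0
        for age in (42, 67):
            assert t.compute_egfr_ckdepi(kappa, age, sex) == pytest.approx(
                141 * female * 0.993**age, rel=1e-12
            )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            t.compute_egfr_ckdepi(0.0, 50, "F")
        with pytest.raises(ValueError):
            t.compute_egfr_ckdepi(1.0, -3, "M")


class TestHandFixture:
    def test_attrition_counts(self, ten_person_registry):
        bundle, exp = ten_person_registry
        cohort, log = t.build_cohort(bundle)
        assert len(cohort) == exp["n_cohort"]
        frame = log.to_frame().set_index("filter")
        for name, ids in exp["excluded"].items():
            assert frame.loc[name, "n_excluded"] == len(ids), name
        # count-conserving attrition
        assert frame["n_excluded"].sum() + len(cohort) == 10
        assert frame["n_remaining"].is_monotonic_decreasing

    def test_exposure_and_mediators(self, ten_person_registry):
        bundle, exp = ten_person_registry
        cohort, _ = t.build_cohort(bundle)
        got = cohort.set_index("person_id")
        assert got["exposure"].to_dict() == exp["exposure"]
        for pid, v in exp["m_statin"].items():
            assert got.loc[pid, "m_statin"] == v, pid
        for pid, v in exp["m_rasi"].items():
            assert got.loc[pid, "m_rasi"] == v, pid

    def test_followup_and_tie_precedence(self, ten_person_registry):
        bundle, exp = ten_person_registry
        cohort, _ = t.build_cohort(bundle)
        got = cohort.set_index("person_id")
        for pid, (years, event, etype) in exp["followup"].items():
            assert got.loc[pid, "followup_years"] == pytest.approx(years, abs=1e-12)
            assert got.loc[pid, "event"] == event
            assert got.loc[pid, "event_type"] == etype

    def test_covariate_lookbacks(self, ten_person_registry):
        bundle, exp = ten_person_registry
        cohort, _ = t.build_cohort(bundle)
        got = cohort.set_index("person_id")
        for pid, v in exp["hf"].items():
            assert got.loc[pid, "hf"] == v
        assert got.loc["H06", "cancer"] == 0  # discharge 11 years back: outside lookback
        for pid, v in exp["egfr_band"].items():
            assert got.loc[pid, "egfr_band"] == v

    def test_upper_band_exclusion_is_that_filter(self, ten_person_registry):
        bundle, _ = ten_person_registry
        _, log = t.build_cohort(bundle)
        frame = log.to_frame().set_index("filter")
        assert frame.loc["first HbA1c within 48-57 band", "n_excluded"] == 1

    def test_idempotence_on_eligible_subset(self, ten_person_registry):
        bundle, _ = ten_person_registry
        cohort, _ = t.build_cohort(bundle)
        ids = set(cohort["person_id"])
        sub = t.RegistryBundle(
            bundle.persons[bundle.persons["person_id"].isin(ids)].reset_index(drop=True),
            bundle.labs[bundle.labs["person_id"].isin(ids)].reset_index(drop=True),
            bundle.prescriptions[bundle.prescriptions["person_id"].isin(ids)].reset_index(drop=True),
            bundle.diagnoses[bundle.diagnoses["person_id"].isin(ids)].reset_index(drop=True),
        )
        cohort2, _ = t.build_cohort(sub)
        pd.testing.assert_frame_equal(
            cohort.sort_values("person_id").reset_index(drop=True),
            cohort2.sort_values("person_id").reset_index(drop=True),
        )


class TestClassification:
    def test_four_groups(self):
        assert classify_exposure(True, 45) == "WC_GLDT"
        assert classify_exposure(True, 50) == "PC_GLDT"
        assert classify_exposure(False, 45) == "REMISSION"
        assert classify_exposure(False, 50) == "PERSISTENT"

    def test_missing_qualifying_value_raises(self):
        with pytest.raises(ClassificationError):
            classify_exposure(True, float("nan"))

    def test_gldt_without_post_gldt_hba1c_filtered_upstream(self, ten_person_registry):
        bundle, _ = ten_person_registry
        # H01 given GLDT on day 150, after the only follow-up HbA1c (day 100):
        # no post-GLDT measurement -> excluded at the follow-up filter
        rx = pd.concat(
            [
                bundle.prescriptions,
                pd.DataFrame(
                    [{
                        "person_id": "H01",
                        "dispense_date": pd.Timestamp("2015-01-01") + pd.Timedelta(days=150),
                        "atc_code": "A10BB01",
                    }]
                ),
            ],
            ignore_index=True,
        )
        mod = t.RegistryBundle(bundle.persons, bundle.labs, rx, bundle.diagnoses)
        cohort, log = t.build_cohort(mod)
        assert "H01" not in set(cohort["person_id"])
        frame = log.to_frame().set_index("filter")
        assert frame.loc["follow-up HbA1c before index (post-GLDT if on GLDT)", "n_excluded"] == 1


class TestMediatorWindow:
    first = pd.Timestamp("2015-01-01")
    index = pd.Timestamp("2015-06-30")

    def _rx(self, rows):
        return pd.DataFrame(
            [{"person_id": "P1", "dispense_date": d, "atc_code": a} for d, a in rows]
        )

    def test_dispense_on_index_date_counts(self):
        rx = self._rx([(self.index, "C10AA05")])
        assert derive_mediators(rx, self.first, self.index) == (1, 0)

    def test_dispense_on_first_date_does_not_count(self):
        rx = self._rx([(self.first, "C10AA05")])
        assert derive_mediators(rx, self.first, self.index) == (0, 0)

    def test_repeats_idempotent(self):
        rx = self._rx(
            [(self.first + pd.Timedelta(days=5), "C09AA02"),
             (self.first + pd.Timedelta(days=90), "C09AA02")]
        )
        assert derive_mediators(rx, self.first, self.index) == (0, 1)

    def test_empty_prescriptions(self):
        assert derive_mediators(self._rx([]), self.first, self.index) == (0, 0)


class TestSimulatorAgreement:
    def test_zero_violation_cohort_equals_ground_truth(self):
        cfg = t.SimulationConfig(n_persons=1500, seed=77)
        bundle = t.generate_registry(cfg)
        cohort, log = t.build_cohort(bundle)
        truth = bundle.truth
        assert len(cohort) == len(truth) == cfg.n_persons
        merged = cohort.merge(truth, on="person_id", suffixes=("", "_t"))
        for col in (
            "exposure", "m_statin", "m_rasi", "age_band", "sex", "cohabitation",
            "income_quartile", "ethnicity", "requester", "first_hba1c_band",
            "egfr_band", "hf", "af", "copd_asthma", "cancer", "event", "event_type",
        ):
            assert (merged[col] == merged[f"{col}_t"]).all(), col
        assert np.allclose(merged["followup_years"], merged["followup_years_t"], atol=1e-12)

    def test_sensitivity_index_365(self):
        cfg = t.SimulationConfig(n_persons=600, seed=31)
        cfg.censor.index_offset_days = 365
        bundle = t.generate_registry(cfg)
        cohort, _ = t.build_cohort(bundle, t.EligibilityConfig(index_offset_days=365))
        merged = cohort.merge(bundle.truth, on="person_id", suffixes=("", "_t"))
        assert len(merged) == cfg.n_persons
        assert (merged["exposure"] == merged["exposure_t"]).all()

    def test_schema_error_names_table_and_column(self, small_registry):
        bundle, _ = small_registry
        broken = t.RegistryBundle(
            bundle.persons.drop(columns=["birth_date"]),
            bundle.labs, bundle.prescriptions, bundle.diagnoses,
        )
        with pytest.raises(SchemaError, match="persons.*birth_date"):
            t.build_cohort(broken)

    def test_hypertension_exclusion_toggle(self, small_registry):
        bundle, _ = small_registry
        base, _ = t.build_cohort(bundle)
        excl, log = t.build_cohort(bundle, t.EligibilityConfig(exclude_hypertension=True))
        first = (
            bundle.labs[(bundle.labs["analyte"] == "HbA1c") & (bundle.labs["value"] >= 48)]
            .groupby("person_id")["sample_date"].min()
        )
        ht = bundle.diagnoses[
            bundle.diagnoses["icd10_code"].str.startswith(("I10", "I11", "I12", "I13", "I15"))
        ].merge(first.rename("first"), left_on="person_id", right_index=True)
        ht_ids = set(ht.loc[ht["discharge_date"] <= ht["first"], "person_id"])
        assert len(base) - len(excl) == len(ht_ids & set(base["person_id"]))
        assert ht_ids.isdisjoint(set(excl["person_id"]))
        names = [s[0] for s in log.steps]
        assert "no hypertension prior to first HbA1c" in names

    def test_empty_eligible_set_returns_empty_cohort_with_log(self, ten_person_registry):
        bundle, _ = ten_person_registry
        cfg = t.EligibilityConfig(age_min=20, age_max=25)
        cohort, log = t.build_cohort(bundle, cfg)
        assert len(cohort) == 0
        assert log.steps[-1][2] == 0
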