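"""Eligibility cascade, outcome derivation and descriptive reporting."""

import numpy as np
import pandas as pd
import pytest

from emusurv import (SimConfig, apply_eligibility, derive_outcomes,
                     descriptive_table, drop_incomplete, impute_treatment_date,
                     simulate_claims)


class TestEligibility:
    def test_ten_claim_fixture_yields_five_subjects(self, ten_claims, codes):
        eligible, log = apply_eligibility(ten_claims, codes)
        assert len(eligible) == 5
        assert set(eligible["beneficiary_id"]) == {"A", "B", "G", "H", "I"}
        steps = {c: e for c, e, _ in log.steps}
        assert steps["age under 65 at diagnosis"] == 2
        assert steps["conversion (both procedure sets)"] == 1
        assert steps["under 12 months prior enrollment"] == 1
        assert steps["later claim of same beneficiary"] == 1

    def test_conversion_claim_excluded(self, codes):
        claims = pd.DataFrame([{
            "beneficiary_id": "X", "admission_date": "2012-01-01",
            "discharge_date": "2012-01-05", "treatment_date": "2012-01-01",
            "diagnosis_codes": "DX_RAAA",
            "procedure_codes": "PROC_EVAR;PROC_OAR", "age_at_admission": 70,
            "sex": "male", "race": "white", "enrollment_start": "2010-01-01",
            "enrollment_end": "", "death_date": ""}])
        eligible, log = apply_eligibility(claims, codes)
        assert len(eligible) == 0
        assert {c: e for c, e, _ in log.steps}[
            "conversion (both procedure sets)"] == 1

    def test_empty_input(self, codes):
        cols = ["beneficiary_id", "admission_date", "discharge_date",
                "treatment_date", "diagnosis_codes", "procedure_codes",
                "age_at_admission", "sex", "race", "enrollment_start",
                "enrollment_end", "death_date"]
        eligible, log = apply_eligibility(pd.DataFrame(columns=cols), codes)
        assert len(eligible) == 0
        assert all(e == 0 for _, e, _ in log.steps)

    def test_unparseable_dates_rejected_with_log(self, ten_claims, codes):
        bad = ten_claims.copy()
        bad.loc[0, "admission_date"] = "not-a-date"
        eligible, log = apply_eligibility(bad, codes)
        assert {c: e for c, e, _ in log.steps}["unparseable dates"] == 1
        assert "A" not in set(eligible["beneficiary_id"])

    def test_idempotence(self, ten_claims, codes):
        eligible, _ = apply_eligibility(ten_claims, codes)
        again, log2 = apply_eligibility(eligible, codes)
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True), eligible.reset_index(drop=True))

    def test_count_conservation_every_step(self, ten_claims, codes):
        _, log = apply_eligibility(ten_claims, codes)
        for prev, cur in zip(log.steps, log.steps[1:]):
            assert cur[1] + cur[2] == prev[2]

    def test_missing_code_list_errors(self, ten_claims, codes):
        bad = dict(codes)
        bad["rupture_dx"] = []
        with pytest.raises(ValueError, match="rupture_dx"):
            apply_eligibility(ten_claims, bad)


class TestImputation:
    def test_missing_replaced_by_admission(self):
        df = pd.DataFrame([
            {"admission_date": "2012-03-01", "treatment_date": ""},
            {"admission_date": "2012-04-01", "treatment_date": "2012-04-02"},
        ])
        out, frac = impute_treatment_date(df)
        assert out.loc[0, "treatment_date"] == "2012-03-01"
        assert out.loc[1, "treatment_date"] == "2012-04-02"  # unchanged
        assert frac == 0.5

    def test_reported_fraction(self):
        df = pd.DataFrame({"admission_date": ["2012-01-01"] * 1000,
                           "treatment_date": [""] * 50 + ["2012-01-01"] * 950})
        _, frac = impute_treatment_date(df)
        assert frac == pytest.approx(0.05)


def _claim_for_outcomes(death="", discharge="2012-01-06", eend=""):
    return pd.DataFrame([{
        "beneficiary_id": "A", "admission_date": "2012-01-01",
        "discharge_date": discharge, "treatment_date": "2012-01-01",
        "diagnosis_codes": "DX_RAAA", "procedure_codes": "PROC_EVAR",
        "age_at_admission": 70, "sex": "male", "race": "white",
        "enrollment_start": "2010-01-01", "enrollment_end": eend,
        "death_date": death}])


class TestOutcomes:
    def test_death_within_periop_window_is_event_for_both(self, codes):
        # treatment day 0, discharge day 5, death day 20
        out = derive_outcomes(_claim_for_outcomes("2012-01-21"), codes,
                              study_end="2014-01-01")
        assert (out.loc[0, "y_short"], out.loc[0, "d_short"]) == (20, 1)
        assert (out.loc[0, "y_long"], out.loc[0, "d_long"]) == (20, 1)

    def test_death_after_periop_window_censors_short(self, codes):
        # death day 40 > discharge(5) + 30 = 35
        out = derive_outcomes(_claim_for_outcomes("2012-02-10"), codes,
                              study_end="2014-01-01")
        assert (out.loc[0, "y_short"], out.loc[0, "d_short"]) == (35, 0)
        assert (out.loc[0, "y_long"], out.loc[0, "d_long"]) == (40, 1)

    def test_administrative_censoring_without_death(self, codes):
        out = derive_outcomes(_claim_for_outcomes(), codes,
                              study_end="2014-09-27")  # day 1000
        assert (out.loc[0, "y_long"], out.loc[0, "d_long"]) == (1000, 0)

    def test_loss_to_followup_censors_before_study_end(self, codes):
        out = derive_outcomes(_claim_for_outcomes(eend="2012-06-29"), codes,
                              study_end="2014-01-01")
        assert (out.loc[0, "y_long"], out.loc[0, "d_long"]) == (180, 0)

    def test_death_before_treatment_rejected(self, codes):
        with pytest.raises(ValueError, match="death before treatment"):
            derive_outcomes(_claim_for_outcomes("2011-12-30"), codes)

    def test_short_time_le_long_time_on_simulated_claims(self, codes):
        claims = simulate_claims(SimConfig(n_beneficiaries=300, seed=21,
                                           missing_covariate_frac=0.0))
        eligible, _ = apply_eligibility(claims, codes)
        eligible, _ = impute_treatment_date(eligible)
        cohort = derive_outcomes(eligible, codes)
        assert (cohort["y_short"] <= cohort["y_long"] + 1e-9).all()
        assert (cohort.loc[cohort["d_short"] == 1, "d_long"] == 1).all()


class TestDropIncomplete:
    def test_planted_missing_removed(self):
        cohort, _ = __import__("emusurv").simulate_cohort(
            SimConfig(n_beneficiaries=50, seed=1))
        cohort = cohort.copy()
        cohort.loc[[3, 7, 11], "race"] = None
        out, removed = drop_incomplete(cohort)
        assert removed == 3 and len(out) == 47

    def test_identity_when_complete(self):
        cohort, _ = __import__("emusurv").simulate_cohort(
            SimConfig(n_beneficiaries=50, seed=1))
        out, removed = drop_incomplete(cohort)
        assert removed == 0 and len(out) == 50

    def test_all_missing_warns_and_empties(self):
        cohort, _ = __import__("emusurv").simulate_cohort(
            SimConfig(n_beneficiaries=5, seed=1))
        cohort = cohort.copy()
        cohort["race"] = None
        with pytest.warns(UserWarning):
            out, removed = drop_incomplete(cohort)
        assert removed == 5 and len(out) == 0


class TestDescriptiveTable:
    def test_incidence_percentages_match_reference(self, table1_cohort):
        t = descriptive_table(table1_cohort).set_index("variable")
        assert t.loc["all-cause mortality", "arm1_pct"] == pytest.approx(61.36, abs=5e-3)
        assert t.loc["all-cause mortality", "arm0_pct"] == pytest.approx(65.75, abs=5e-3)

    def test_identical_arms_chi2_p_one(self):
        cohort, _ = __import__("emusurv").simulate_cohort(
            SimConfig(n_beneficiaries=200, seed=4))
        mirrored = cohort.copy()
        mirrored["treatment"] = 1 - cohort["treatment"].to_numpy()
        # stack a cohort against its own mirror: each covariate identical by arm
        both = pd.concat([cohort.assign(treatment=1),
                          cohort.assign(treatment=0)], ignore_index=True)
        t = descriptive_table(both)
        ps = t.loc[t["kind"].isin(["binary", "categorical"]), "p_value"].dropna()
        assert np.allclose(ps, 1.0)

    def test_chi2_statistic_hand_value(self):
        # 2x2 table (20,80 / 40,60): sum (O-E)^2/E = 9.5238..., no correction
        from emusurv.cohort import _chi2_p
        stat, p = _chi2_p(np.array([[20, 80], [40, 60]]))
        assert stat == pytest.approx(9.5238, abs=1e-3)

    def test_zero_variance_continuous_p_undefined(self, table1_cohort):
        c = table1_cohort.copy()
        c["age"] = 75.0
        t = descriptive_table(c).set_index("variable")
        assert np.isnan(t.loc["age", "p_value"])

    def test_requires_two_per_arm(self, table1_cohort):
        with pytest.raises(ValueError):
            descriptive_table(table1_cohort.head(3))
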