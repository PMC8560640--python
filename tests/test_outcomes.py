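"""Cohort statistics: group comparisons, regression, Cox, Kaplan-Meier."""

import numpy as np
import pandas as pd
import pytest

from pulmotransit.outcomes import (CoxPerSD, compare_groups, correlate,
                                   fit_cox_per_sd, fit_log_ptt_model,
                                   km_dichotomized,
                                   sensitivity_censor_early_revasc)
from pulmotransit.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(n_subjects=1500, seed=21,
                                        log_hr_per_sd_ptt=np.log(1.5)))


class TestCompareGroups:
    def test_identical_categorical_groups_give_p_one(self):
        df = generate_cohort(CohortConfig(n_subjects=200, seed=3))
        doubled = pd.concat([df.assign(grp=0), df.assign(grp=1)])
        out = compare_groups(doubled, "grp", variables=["diabetes", "male"])
        assert np.allclose(out["p_value"], 1.0)

    def test_small_group_gets_descriptive_output_only(self):
        df = generate_cohort(CohortConfig(n_subjects=100, seed=4))
        df["grp"] = 0
        df.loc[df.index[:2], "grp"] = 1
        out = compare_groups(df, "grp", variables=["ptt", "diabetes"])
        assert out["p_value"].isna().all()
        assert out["test"].eq("none").all()

    def test_shifted_ptt_detected_by_rank_test(self):
        # +1.5 s in a 60-subject event group vs 900 controls at SD ~2.4 s
        detected = 0
        for seed in range(10):
            df = generate_cohort(CohortConfig(n_subjects=960, seed=100 + seed))
            df["grp"] = 0
            idx = df.sample(60, random_state=seed).index
            df.loc[idx, "grp"] = 1
            df.loc[idx, "ptt"] += 1.5
            out = compare_groups(df, "grp", variables=["ptt"])
            detected += out["p_value"].iloc[0] < 0.05
        assert detected >= 8

    def test_single_group_rejected(self):
        df = generate_cohort(CohortConfig(n_subjects=50, seed=5))
        df["grp"] = 0
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(df, "grp")


class TestCorrelate:
    def test_perfect_monotone_relationships(self):
        df = pd.DataFrame({"x": np.arange(50.0)})
        df["up"] = df["x"] ** 2
        df["down"] = -df["x"]
        out = correlate(df, [("x", "up"), ("x", "down")])
        assert out["rho"].tolist() == pytest.approx([1.0, -1.0])

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"x": np.arange(20.0), "c": np.ones(20)})
        out = correlate(df, [("x", "c")])
        assert np.isnan(out["rho"].iloc[0])
        assert out["flag"].iloc[0] == "constant_variable"

    def test_generated_sign_structure(self, cohort):
        out = correlate(cohort, [("heart_rate", "ptt"), ("lvef", "ptt"),
                                 ("la_area_index", "ptt")])
        assert (np.sign(out["rho"]) == [-1, -1, 1]).all()


class TestLogPttRegression:
    def test_zero_noise_betas_recovered_exactly(self):
        cfg = CohortConfig(n_subjects=600, log_ptt_noise_sd=0.0, seed=11)
        df = generate_cohort(cfg)
        res = fit_log_ptt_model(df)
        for cov, beta in cfg.log_ptt_betas.items():
            assert res.table.loc[cov, "beta"] == pytest.approx(beta, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_intercept_is_mean_log_outcome_for_centered_single_covariate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 300)
        x -= x.mean()
        df = pd.DataFrame({"x": x, "ptt": np.exp(2.0 + 0.1 * x + rng.normal(0, 0.05, 300))})
        res = fit_log_ptt_model(df, covariates=("x",))
        assert res.table.loc["const", "beta"] == pytest.approx(
            np.log(df["ptt"]).mean(), abs=1e-10)

    def test_collinear_design_rejected_with_names(self, cohort):
        df = cohort.copy()
        df["lvef_twin"] = df["lvef"] * 2.0
        with pytest.raises(ValueError, match="collinear.*(lvef|lvef_twin)"):
            fit_log_ptt_model(df, covariates=("lvef", "lvef_twin", "age"))

    def test_too_few_complete_cases_rejected(self):
        df = generate_cohort(CohortConfig(n_subjects=50, seed=1))
        with pytest.raises(ValueError, match="complete cases"):
            fit_log_ptt_model(df)


class TestCoxPerSd:
    def test_scaled_and_raw_fits_are_equivalent(self, cohort):
        sd = cohort["ptt"].std(ddof=1)
        scaled = fit_cox_per_sd(cohort)
        raw = fit_cox_per_sd(cohort, scale_sd=1.0)
        assert scaled.hr_per_sd == pytest.approx(
            np.exp(np.log(raw.hr_per_sd) * sd), rel=1e-10)
        assert scaled.predictor_sd == pytest.approx(sd)

    def test_ci_brackets_estimate_and_chi_square_positive(self, cohort):
        res = fit_cox_per_sd(cohort)
        assert res.ci95[0] < res.hr_per_sd < res.ci95[1]
        assert res.model_chi_square > 0
        assert set(res.schoenfeld_p) >= {"age", "lvef", "diabetes"}

    def test_constant_predictor_rejected(self, cohort):
        df = cohort.copy()
        df["ptt"] = 8.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox_per_sd(df)

    def test_zero_events_rejected(self):
        df = generate_cohort(CohortConfig(n_subjects=300, censor_rate=1.0, seed=2))
        with pytest.raises(ValueError, match="events"):
            fit_cox_per_sd(df)

    def test_penalized_refit_reported_with_metadata(self, cohort):
        res = CoxPerSD(penalized_refit=True).fit(cohort).result_
        assert res.firth_adjusted is not None
        assert res.firth_adjusted["penalty"] == "l2_partial_likelihood"
        # penalization shrinks the log-HR toward zero
        assert abs(np.log(res.firth_adjusted["hr_per_sd"])) \
            <= abs(np.log(res.hr_per_sd)) + 1e-9

    def test_pbvi_and_ptt_hazards_agree_in_direction(self, cohort):
        hr_ptt = fit_cox_per_sd(cohort, predictor="ptt").hr_per_sd
        hr_pbvi = fit_cox_per_sd(cohort, predictor="pbvi").hr_per_sd
        assert (hr_ptt - 1.0) * (hr_pbvi - 1.0) > 0


class TestKaplanMeier:
    def test_four_subject_logrank_matches_hand_computation(self):
        # events at t=1 (A) and t=2,4 (B), one censoring at t=3 (A):
        # O-E = 1/6, V = 1/4 + 2/9 = 17/36, chi2 = (1/6)^2/(17/36) = 1/17
        df = pd.DataFrame({"b": [0.0, 0.0, 1.0, 1.0],
                           "followup_time": [1.0, 3.0, 2.0, 4.0],
                           "event": [1, 0, 1, 1]})
        res = km_dichotomized(df, "b", cutoff=0.5)
        assert res.logrank_statistic == pytest.approx(1.0 / 17.0, rel=1e-9)

    def test_all_censored_curves_stay_at_one(self):
        df = pd.DataFrame({"b": np.r_[np.zeros(10), np.ones(10)],
                           "followup_time": np.full(20, 24.0),
                           "event": np.zeros(20, dtype=int)})
        res = km_dichotomized(df, "b", cutoff=0.5)
        assert res.survival_at(24.0) == pytest.approx((1.0, 1.0))

    def test_mean_cutoff_splits_cohort(self, cohort):
        res = km_dichotomized(cohort, "ptt")
        assert res.cutoff == pytest.approx(cohort["ptt"].mean())
        assert res.n_low + res.n_high == len(cohort)

    def test_empty_stratum_rejected_with_advice(self, cohort):
        with pytest.raises(ValueError, match="cutoff"):
            km_dichotomized(cohort, "ptt", cutoff=1000.0)


class TestEarlyRevascSensitivity:
    def test_no_revascularization_reproduces_base_fit(self, cohort):
        base = fit_cox_per_sd(cohort)
        sens = sensitivity_censor_early_revasc(cohort)
        assert sens.hr_per_sd == base.hr_per_sd
        assert sens.ci95 == base.ci95

    def test_universal_day1_revascularization_removes_all_events(self, cohort):
        df = cohort.copy()
        df["early_revasc_days"] = 1.0
        with pytest.raises(ValueError, match="events"):
            sensitivity_censor_early_revasc(df)

    def test_random_small_subset_shifts_hr_under_5_percent(self):
        df = generate_cohort(CohortConfig(n_subjects=2000, seed=31,
                                          log_hr_per_sd_ptt=np.log(1.5),
                                          early_revasc_fraction=0.02))
        base = fit_cox_per_sd(df)
        sens = sensitivity_censor_early_revasc(df)
        assert abs(sens.hr_per_sd - base.hr_per_sd) / base.hr_per_sd < 0.05
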