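import numpy as np
import pandas as pd
import pytest

from volscroll import (
    CohortParams,
    UndefinedMetricError,
    ValidationError,
    fit_binomial_glmm,
    fit_binomial_ladder,
    fit_lmm_ladder,
    level1_r2,
    marginal_effect,
    records_to_frame,
    select_best,
    simulate_cohort,
)
from volscroll.models import ModelFit, FixedEffect, VarianceComponents


@pytest.fixture(scope="module")
def cohort_df():
    records, _ = simulate_cohort(CohortParams(n_residents=250), seed=11)
    return records_to_frame(records)


@pytest.fixture(scope="module")
def lmm_ladder(cohort_df):
    return fit_lmm_ladder(cohort_df, "PercTimeFullRunsAvg")


class TestLmmLadder:
    def test_four_models_fitted_by_full_ml(self, lmm_ladder):
        assert [f.name for f in lmm_ladder] == [f"Model {i}" for i in range(4)]
        assert all(f.kind == "linear" for f in lmm_ladder)

    def test_deviance_non_increasing_along_ladder(self, lmm_ladder):
        devs = [f.deviance for f in lmm_ladder if f.converged]
        assert all(b <= a + 1e-6 for a, b in zip(devs, devs[1:]))

    def test_recovers_generating_parameters(self, lmm_ladder):
        m2 = lmm_ladder[2]
        b = {fe.name: fe.b for fe in m2.fixed}
        # generating values 20.19 / -0.94; single-cohort sampling error applies
        assert b["Intercept"] == pytest.approx(20.19, abs=1.5)
        assert b["tr_time"] == pytest.approx(-0.94, abs=0.45)
        assert m2.var.sigma2_e == pytest.approx(81.56, rel=0.15)

    def test_zero_variance_outcome_collapses(self):
        df = pd.DataFrame(
            {
                "resident_id": ["a", "a", "b", "b"],
                "drpt_id": list("wxyz"),
                "tr_time": [1.0, 2.0, 1.5, 2.5],
                "drpt_diff": [0.1, 0.2, 0.1, 0.2],
                "perc_time_full_runs_avg": [25.0] * 4,
                "perc_time_rel_area_avg": [50.0] * 4,
                "n_correct": [1] * 4,
                "n_questions": [2] * 4,
            }
        )
        ladder = fit_lmm_ladder(df, "PercTimeFullRunsAvg")
        m1 = ladder[1]
        slope = m1.effect("tr_time").b
        assert slope == pytest.approx(0.0, abs=1e-8)
        assert m1.var.sigma2_e == pytest.approx(0.0, abs=1e-8)

    def test_robust_and_model_ses_agree_on_clean_simulations(self, cohort_df):
        robust = fit_lmm_ladder(cohort_df, "PercTimeFullRunsAvg", robust=True)[2]
        naive = fit_lmm_ladder(cohort_df, "PercTimeFullRunsAvg", robust=False)[2]
        for fe_r, fe_n in zip(robust.fixed, naive.fixed):
            assert fe_r.se == pytest.approx(fe_n.se, rel=0.25)


class TestSelectBest:
    def test_table_structure_prefers_model_2_in_most_replicates(self):
        # cohorts carry real TrTime and DRPTdiff effects but no random slope;
        # with only 9 distinct tests the DRPTdiff contrast is modest, so the
        # claim is majority preference over study-sized replicates
        from volscroll.models import lr_test

        wins = 0
        for seed in range(5):
            records, _ = simulate_cohort(CohortParams(n_residents=650), seed=seed)
            ladder = fit_lmm_ladder(records, "PercTimeFullRunsAvg")
            _, _, p = lr_test(ladder[1], ladder[2])
            wins += p < 0.05
        assert wins >= 3

    def test_no_simulated_effects_keeps_intercept_only(self):
        params = CohortParams(
            n_residents=150,
            fullruns=(20.0, 0.0, 0.0, 80.0, 10.0),
            relarea=(50.0, 0.0, 0.0, 130.0, 5.0),
        )
        records, _ = simulate_cohort(params, seed=3)
        ladder = fit_lmm_ladder(records, "PercTimeFullRunsAvg")
        assert select_best(ladder).name == "Model 0"

    def test_needs_two_converged_fits(self, lmm_ladder):
        with pytest.raises(ValidationError):
            select_best(lmm_ladder[:1])


class TestLevel1R2:
    def test_identical_fits_give_zero(self, lmm_ladder):
        assert level1_r2(lmm_ladder[0], lmm_ladder[0]) == 0.0

    def test_halved_residual_variance_gives_half(self):
        def fake(s2e):
            return ModelFit(
                name="m", kind="linear", fixed=(),
                var=VarianceComponents(sigma2_e=s2e, sigma2_u0=1.0),
                deviance=0.0, n_params=2, n_obs=10, n_groups=5, converged=True,
            )

        assert level1_r2(fake(40.0), fake(80.0)) == pytest.approx(0.5)

    def test_zero_null_variance_undefined(self):
        def fake(s2e):
            return ModelFit(
                name="m", kind="linear", fixed=(),
                var=VarianceComponents(sigma2_e=s2e, sigma2_u0=1.0),
                deviance=0.0, n_params=2, n_obs=10, n_groups=5, converged=True,
            )

        with pytest.raises(UndefinedMetricError):
            level1_r2(fake(0.0), fake(0.0))


class TestBinomialGlmm:
    def test_matches_lme4_glmer_oracle(self):
        # frozen reference: lme4::glmer(cbind(n_correct, n_questions-n_correct)
        #   ~ tr_time + drpt_diff + (1|resident_id), family=binomial, nAGQ=20)
        # on the seed-42, 60-resident cohort regenerated below
        records, _ = simulate_cohort(CohortParams(n_residents=60), seed=42)
        fit = fit_binomial_glmm(records_to_frame(records), ["tr_time", "drpt_diff"])
        expected_b = {"Intercept": -0.948192, "tr_time": 0.345464, "drpt_diff": 5.184468}
        expected_se = {"Intercept": 0.156157, "tr_time": 0.040806, "drpt_diff": 0.898642}
        for fe in fit.fixed:
            assert fe.b == pytest.approx(expected_b[fe.name], abs=2e-4)
            assert fe.se == pytest.approx(expected_se[fe.name], abs=2e-4)
        assert fit.var.sigma2_u0 == pytest.approx(0.010060, abs=5e-4)

    def test_aggregated_equals_exploded_bernoulli_rows(self):
        records, _ = simulate_cohort(CohortParams(n_residents=40), seed=8)
        df = records_to_frame(records)
        agg = fit_binomial_glmm(df, ["tr_time"])
        rows = []
        for r in df.itertuples(index=False):
            for i in range(int(r.n_questions)):
                rows.append(
                    {
                        "resident_id": r.resident_id,
                        "tr_time": r.tr_time,
                        "n_correct": 1 if i < r.n_correct else 0,
                        "n_questions": 1,
                    }
                )
        exploded = fit_binomial_glmm(pd.DataFrame(rows), ["tr_time"])
        for fe_a, fe_e in zip(agg.fixed, exploded.fixed):
            assert fe_a.b == pytest.approx(fe_e.b, abs=1e-4)
        assert agg.var.sigma2_u0 == pytest.approx(exploded.var.sigma2_u0, abs=1e-3)

    def test_all_correct_data_flagged_as_separation(self):
        df = pd.DataFrame(
            {
                "resident_id": ["a", "a", "b", "b", "c", "c"],
                "tr_time": [1.0, 2.0, 1.5, 2.5, 3.0, 4.0],
                "n_correct": [4] * 6,
                "n_questions": [4] * 6,
            }
        )
        fit = fit_binomial_glmm(df, ["tr_time"])
        assert not fit.converged

    def test_odds_ratio_is_exp_b_and_ci_brackets_it(self, cohort_df):
        ladder = fit_binomial_ladder(cohort_df)
        m = ladder[1]
        fe = m.effect("tr_time")
        assert fe.or_ == pytest.approx(np.exp(fe.b))
        assert fe.ci[0] < fe.or_ < fe.ci[1]


class TestMarginalEffect:
    @staticmethod
    def _linear_fit(b, name="drpt_diff"):
        return ModelFit(
            name="m", kind="linear",
            fixed=(FixedEffect(name=name, b=b, se=1.0, p=0.01),),
            var=VarianceComponents(sigma2_e=1.0, sigma2_u0=1.0),
            deviance=0.0, n_params=3, n_obs=10, n_groups=5, converged=True,
        )

    def test_linear_effect_is_b_times_delta(self):
        assert marginal_effect(self._linear_fit(6.70), "drpt_diff", 0.1) == pytest.approx(0.67)
        assert marginal_effect(self._linear_fit(6.70), "drpt_diff", 0.24) == pytest.approx(1.608)
        assert marginal_effect(self._linear_fit(-57.47), "drpt_diff", 0.24) == pytest.approx(-13.79, abs=0.005)

    def test_logistic_effect_is_or_power_delta(self):
        fit = ModelFit(
            name="m", kind="logistic",
            fixed=(FixedEffect(name="tr_time", b=0.338, se=0.02, p=0.001,
                               or_=float(np.exp(0.338)), ci=(1.36, 1.44)),),
            var=VarianceComponents(sigma2_e=None, sigma2_u0=0.056),
            deviance=0.0, n_params=3, n_obs=10, n_groups=5, converged=True,
        )
        assert marginal_effect(fit, "tr_time", 1.0) == pytest.approx(np.exp(0.338))
        assert marginal_effect(fit, "tr_time", 2.0) == pytest.approx(np.exp(0.338) ** 2)

    def test_unknown_predictor_rejected(self):
        with pytest.raises(KeyError):
            marginal_effect(self._linear_fit(1.0), "nope", 0.1)
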