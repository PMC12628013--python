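import subprocess

import numpy as np
import pytest
import statsmodels.api as sm

from revlearn.population_model import (
    MAXIMAL_RANDOM_STRUCTURE,
    ModelDesign,
    RandomStructure,
    build_design,
    fit_population_model,
    full_null_comparison,
    likelihood_ratio_test,
    single_term_tests,
    trim_trials,
)
from revlearn.synthetic_data import generate_glmm_cohort
from revlearn.trial_data import TrialSequence

BETA = {"intercept": 0.2, "trial_z": 0.5, "task_c": -1.0, "colour_c": -0.8}
RE_INT = {"intercept": 0.7}
RS_INT = RandomStructure(terms=("intercept",), correlated=False)
RS_INT_TRIAL = RandomStructure(terms=("intercept", "trial_z"), correlated=False)


@pytest.fixture(scope="module")
def cohort():
    return generate_glmm_cohort(BETA, RE_INT, n_subjects=24,
                                n_trials_range=(15, 60), seed=11)


@pytest.fixture(scope="module")
def design(cohort):
    return build_design(cohort)


@pytest.fixture(scope="module")
def fitted(design):
    return fit_population_model(design, RS_INT, allow_fallback=False)


class TestBuildDesign:
    def test_zscore_and_centring(self):
        seqs = [
            TrialSequence("A", "AL", positive_colour="LB", outcomes=[1, 0, 1, 0, 1]),
            TrialSequence("B", "RL", positive_colour="DB", outcomes=[0, 1, 0, 1, 0]),
        ]
        d = build_design(seqs)
        f = d.frame
        assert f["trial_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert f["trial_z"].std(ddof=1) == pytest.approx(1.0)
        # balanced binary codes centre at -0.5 / +0.5
        assert sorted(f["task_c"].unique()) == pytest.approx([-0.5, 0.5])
        assert sorted(f["colour_c"].unique()) == pytest.approx([-0.5, 0.5])
        # per-subject trial 1..5 standardized to symmetric values
        one = f[f["subject_id"] == "A"]["trial_z"].to_numpy()
        assert one[2] != one[1]
        np.testing.assert_allclose(one + one[::-1], 0.0, atol=1e-12)

    def test_unbalanced_codes_have_weighted_mean_zero(self):
        seqs = [
            TrialSequence("A", "AL", outcomes=[1] * 6),
            TrialSequence("B", "AL", outcomes=[0] * 6),
            TrialSequence("B", "RL", outcomes=[0, 1, 1, 0]),
        ]
        d = build_design(seqs)
        assert d.frame["task_c"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_level_task_with_interaction_rejected(self):
        seqs = [
            TrialSequence("A", "AL", outcomes=[1, 0, 1]),
            TrialSequence("B", "AL", outcomes=[0, 1, 1]),
        ]
        with pytest.raises(ValueError, match="single level"):
            build_design(seqs, include_interaction=True)
        d = build_design(seqs, include_interaction=False)
        assert "trial_z:task_c" not in d.fixed_terms()

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            build_design([TrialSequence("A", "AL", outcomes=[1, 0, 1])])


class TestFit:
    def test_recovers_generating_fixed_effects(self, fitted):
        for term, truth in BETA.items():
            est, se = fitted.coef(term), fitted.se(term)
            assert abs(est - truth) < 2.5 * se, term
        assert fitted.converged
        assert 0.3 < fitted.variance_components.loc["intercept", "sd"] < 1.2

    def test_matches_lme4_glmer(self, design):
        """Independent oracle: the same model fitted by lme4's Laplace
        glmer agrees in coefficients, SEs and log-likelihood."""
        fit = fit_population_model(design, RS_INT, allow_fallback=False,
                                   fixed_terms=("intercept", "trial_z", "task_c", "colour_c"))
        csv = design.frame.to_csv(index=False)
        rcode = """
        d <- read.csv("stdin")
        suppressMessages(library(lme4))
        m <- glmer(success ~ trial_z + task_c + colour_c + (1 | subject_id),
                   data = d, family = binomial)
        co <- summary(m)$coefficients
        cat(co[, 1], co[, 2], as.numeric(logLik(m)), sep = "\\n")
        """
        res = subprocess.run(["Rscript", "-e", rcode], input=csv,
                             capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        vals = [float(x) for x in res.stdout.split()]
        est_r, se_r, ll_r = vals[:4], vals[4:8], vals[8]
        np.testing.assert_allclose(fit.fixed_effects["estimate"], est_r, atol=2e-3)
        np.testing.assert_allclose(fit.fixed_effects["se"], se_r, rtol=2e-2)
        assert fit.log_likelihood == pytest.approx(ll_r, abs=0.05)

    def test_zero_variance_generator_matches_plain_logistic(self):
        seqs = generate_glmm_cohort(BETA, {}, n_subjects=20,
                                    n_trials_range=(20, 40), seed=3)
        d = build_design(seqs)
        fit = fit_population_model(d, RS_INT, allow_fallback=False)
        X = np.column_stack([d.column(t) for t in fit.fixed_terms])
        glm = sm.GLM(d.frame["success"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.fixed_effects["estimate"], glm.params, atol=0.05)
        assert fit.variance_components["sd"].iloc[0] < 0.2

    def test_maximal_structure_fits_or_falls_back_with_record(self, design):
        fit = fit_population_model(design, MAXIMAL_RANDOM_STRUCTURE)
        assert fit.converged
        assert fit.fallback_rung >= 0
        assert fit.log_likelihood <= 0

    def test_single_subject_rejected(self):
        seqs = [TrialSequence("A", "AL", outcomes=[1, 0] * 10)]
        with pytest.raises(ValueError):
            build_design(seqs)


class TestLikelihoodRatio:
    def test_identical_models_give_zero_statistic(self, fitted):
        comp = likelihood_ratio_test(fitted, fitted)
        assert comp.statistic == 0.0
        assert comp.df == 0
        assert comp.p_value == 1.0

    def test_full_beats_nested_reduction(self, design, fitted):
        reduced = fit_population_model(
            design, RS_INT, fixed_terms=("intercept", "colour_c"),
            allow_fallback=False,
        )
        comp = likelihood_ratio_test(fitted, reduced)
        assert comp.statistic >= 0
        assert comp.df == 3  # trial_z, task_c and their interaction dropped
        assert comp.p_value < 0.001  # strong generated trial and task effects

    def test_non_nested_rejected(self, design, fitted):
        other = fit_population_model(
            design, RS_INT, fixed_terms=("intercept", "colour_c"),
            allow_fallback=False,
        )
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(other, fitted)  # "full" is smaller

    def test_full_null_comparison_detects_signal(self, design):
        comp, full, null = full_null_comparison(design, RS_INT)
        assert comp.p_value < 0.001
        assert full.log_likelihood >= null.log_likelihood - 1e-6


class TestSingleTermTests:
    def test_workflow_on_no_interaction_cohort(self):
        seqs = generate_glmm_cohort(BETA, RE_INT, n_subjects=24,
                                    n_trials_range=(15, 50), seed=19)
        d = build_design(seqs, include_interaction=True)
        res = single_term_tests(d, RS_INT)
        assert not res["interaction_significant"]
        # with the interaction removed, each generated main effect shows up
        assert res["trial_z"].p_value < 0.01
        assert res["task_c"].p_value < 0.01
        assert res["colour_c"].p_value < 0.05

    def test_significant_interaction_stops_main_effect_tests(self):
        seqs = generate_glmm_cohort(
            {**BETA, "trial_z:task_c": 1.5}, RE_INT, n_subjects=24,
            n_trials_range=(20, 60), seed=23,
        )
        d = build_design(seqs, include_interaction=True)
        res = single_term_tests(d, RS_INT)
        assert res["interaction_significant"]
        assert "trial_z" not in res


class TestTrim:
    def test_truncation_arithmetic(self):
        seqs = [
            TrialSequence("A", "AL", outcomes=[1, 0] * 33),  # 66 trials
            TrialSequence("B", "AL", outcomes=[1, 0] * 10),  # 20 trials
        ]
        trimmed = trim_trials(seqs, 40)
        assert [s.n for s in trimmed] == [40, 20]
        assert sum(s.n for s in trimmed) == sum(min(s.n, 40) for s in seqs)

    def test_trimmed_fit_qualitatively_consistent(self, cohort, fitted):
        trimmed = trim_trials(cohort, 40)
        d40 = build_design(trimmed)
        fit40 = fit_population_model(d40, RS_INT, allow_fallback=False)
        for term in ("trial_z", "task_c", "colour_c"):
            assert np.sign(fit40.coef(term)) == np.sign(fitted.coef(term))
            lo1, hi1 = fitted.confint(term)
            lo2, hi2 = fit40.confint(term)
            assert max(lo1, lo2) <= min(hi1, hi2)  # overlapping 95% CIs
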