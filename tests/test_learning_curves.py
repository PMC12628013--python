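import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from revlearn.criterion import CriterionSpec
from revlearn.learning_curves import (
    batch_logistic_slopes,
    binomial_two_sided_p,
    fit_learning_curve,
    initial_accuracy_assess,
    overall_accuracy_assess,
    post_criterion_assess,
    simulate_null_slopes,
    slope_p_value,
)
from revlearn.trial_data import TrialSequence


class TestFitLearningCurve:
    def test_balanced_symmetric_pattern_has_zero_slope(self):
        # score equation at zero slope: sum (y - ybar) * t = 0 for [0,1,1,0]
        with pytest.warns(UserWarning, match="low-information"):
            fit = fit_learning_curve(np.array([0, 1, 1, 0]))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.converged and not fit.separated

    @pytest.mark.parametrize(
        "outcomes, sign",
        [
            ([1] * 12, 1),
            ([0] * 12, -1),
            ([0] * 6 + [1] * 6, 1),   # step: quasi-complete separation
            ([1] * 6 + [0] * 6, -1),
        ],
    )
    def test_separation_flagged_with_signed_infinity(self, outcomes, sign):
        fit = fit_learning_curve(np.array(outcomes))
        assert fit.separated
        assert fit.slope == sign * np.inf
        assert not fit.finite

    def test_matches_statsmodels_mle(self, rng):
        y = (rng.random(70) < np.linspace(0.3, 0.85, 70)).astype(float)
        fit = fit_learning_curve(y)
        t = sm.add_constant(np.arange(1, 71, dtype=float))
        ref = sm.GLM(y, t, family=sm.families.Binomial()).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-8)
        assert fit.slope_se == pytest.approx(ref.bse[1], rel=1e-4)

    def test_slope_sign_invariant_to_covariate_rescaling(self, learner_sequence):
        # the fitted per-trial slope maps exactly under affine rescaling of t
        fit = fit_learning_curve(learner_sequence)
        y = learner_sequence.outcomes.astype(float)
        t = np.arange(1, y.size + 1, dtype=float)
        z = (t - t.mean()) / t.std(ddof=1)
        ref = sm.GLM(y, sm.add_constant(z), family=sm.families.Binomial()).fit()
        assert np.sign(ref.params[1]) == np.sign(fit.slope)
        assert ref.params[1] / t.std(ddof=1) == pytest.approx(fit.slope, rel=1e-5)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            fit_learning_curve(np.array([1]))


class TestBatchSolver:
    def test_agrees_with_single_fits(self, rng):
        Y = (rng.random((100, 30)) < 0.5).astype(int)
        slopes = batch_logistic_slopes(Y)
        for i in range(0, 100, 7):
            single = fit_learning_curve(Y[i])
            if single.separated:
                assert slopes[i] == single.slope
            else:
                assert slopes[i] == pytest.approx(single.slope, abs=1e-7)


class TestNullSlopes:
    def test_deterministic_under_seed(self):
        a = simulate_null_slopes(30, n_agents=200, seed=9)
        b = simulate_null_slopes(30, n_agents=200, seed=9)
        np.testing.assert_array_equal(a.slopes, b.slopes)

    def test_finite_null_mean_near_zero(self):
        null = simulate_null_slopes(50, n_agents=1000, seed=4)
        assert abs(null.finite_slopes.mean()) < 0.02

    def test_short_sequences_produce_separated_agents(self):
        # at n=4 a monotone all-0/all-1 draw has probability 2/16; more
        # patterns (e.g. 0011) also separate, so markers must appear
        null = simulate_null_slopes(4, n_agents=2000, seed=2)
        assert null.n_separated > 0
        assert null.slopes.size == 2000


class TestSlopePValue:
    def test_definition_with_ties(self):
        null = simulate_null_slopes(20, n_agents=3, seed=0)
        null.slopes = np.array([0.1, 0.2, 0.3])
        assert slope_p_value(0.2, null) == pytest.approx(2 / 3)
        assert slope_p_value(1.0, null) == 0.0
        assert slope_p_value(0.05, null) == 1.0

    def test_infinite_markers_order_correctly(self):
        null = simulate_null_slopes(20, n_agents=4, seed=0)
        null.slopes = np.array([np.inf, 0.2, -np.inf, 0.0])
        assert slope_p_value(0.3, null) == pytest.approx(1 / 4)
        with pytest.warns(UserWarning, match="separated"):
            from revlearn.learning_curves import SlopeFit

            obs = SlopeFit(np.nan, np.inf, np.nan, 20, False, True)
            assert slope_p_value(obs, null) == pytest.approx(1 / 4)

    def test_conservative_variant(self):
        null = simulate_null_slopes(20, n_agents=4, seed=0)
        null.slopes = np.array([0.1, 0.2, 0.3, 0.4])
        assert slope_p_value(0.5, null, conservative=True) == pytest.approx(1 / 5)

    def test_mismatched_n_warns(self):
        null = simulate_null_slopes(30, n_agents=50, seed=1)
        from revlearn.learning_curves import SlopeFit

        obs = SlopeFit(0.0, 0.01, 0.1, 40, True, False)
        with pytest.warns(UserWarning, match="null was simulated"):
            slope_p_value(obs, null)


class TestInitialAccuracy:
    def test_thresholds_match_exact_binomial_quantiles(self):
        # smallest value with CDF >= q for Binomial(12, 0.5): 3/12 and 9/12
        a = initial_accuracy_assess(np.ones(12, dtype=int), seed=0)
        assert a.upper_threshold == pytest.approx(9 / 12)
        assert a.lower_threshold == pytest.approx(3 / 12)
        assert a.classification == "above"

    @pytest.mark.parametrize(
        "k, expected",
        [(12, "above"), (6, "NS"), (1, "below"), (9, "NS")],  # 9/12 not strictly above
    )
    def test_classification_boundaries(self, k, expected):
        y = np.array([1] * k + [0] * (12 - k))
        assert initial_accuracy_assess(y, seed=0).classification == expected

    def test_short_sequences_use_length_matched_null(self):
        a = initial_accuracy_assess(np.ones(9, dtype=int), seed=0)
        assert a.n == 9
        assert a.classification == "above"  # 9/9 beats the Binomial(9,.5) 95th pct


class TestOverallAccuracy:
    def test_two_sided_binomial_examples(self):
        a = overall_accuracy_assess(np.ones(10, dtype=int))
        assert a.p_value == pytest.approx(2 / 1024)
        assert a.classification == "above"
        b = overall_accuracy_assess(np.array([1] * 5 + [0] * 5))
        assert b.p_value == 1.0 and b.classification == "NS"
        c = overall_accuracy_assess(np.zeros(12, dtype=int))
        assert c.classification == "below"
        assert c.p_value == pytest.approx(2 / 4096)

    def test_agrees_with_scipy_exact_test(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(0, n + 1))
            ours = binomial_two_sided_p(k, n)
            # doubled-tail convention; scipy's minlike agrees at p = 0.5
            ref = stats.binomtest(k, n, 0.5).pvalue
            assert ours == pytest.approx(ref, abs=1e-12)


class TestPostCriterion:
    def test_nothing_after_criterion_is_absent(self):
        seq = TrialSequence("B1", "AL", outcomes=[0, 0] + [1] * 10)
        assessment, post_n = post_criterion_assess(seq)
        assert assessment is None and post_n == 0

    def test_sustained_learning_detected(self, rng):
        post = (rng.random(22) < 0.95).astype(int)
        while post.sum() < 20:
            post = (rng.random(22) < 0.95).astype(int)
        seq = TrialSequence("B1", "RL", outcomes=[1] * 10 + post.tolist())
        assessment, post_n = post_criterion_assess(seq)
        assert post_n == 22
        assert assessment.classification == "above"

    def test_chance_continuation_is_ns(self):
        post = [1, 0] * 18 + [1]  # 19/37
        seq = TrialSequence("B1", "RL", outcomes=[0, 0, 0] + [1] * 10 + post)
        assessment, post_n = post_criterion_assess(seq)
        assert post_n == 37
        assert assessment.classification == "NS"

    def test_never_met_is_absent(self):
        seq = TrialSequence("B1", "RL", outcomes=[1, 0] * 20)
        assert post_criterion_assess(seq) == (None, 0)


class TestCalibrationAndPower:
    def test_type_i_error_near_nominal(self, rng):
        """Chance subjects tested against their own nulls reject at ~5%."""
        n_subjects, n_trials = 150, 50
        Y = (rng.random((n_subjects, n_trials)) < 0.5).astype(float)
        obs = batch_logistic_slopes(Y)
        rejections = 0
        for i in range(n_subjects):
            null = simulate_null_slopes(n_trials, n_agents=400, seed=1000 + i)
            if slope_p_value(float(obs[i]), null) < 0.05:
                rejections += 1
        rate = rejections / n_subjects
        # 3 binomial SEs around 0.05 at n=150 is about +/- 0.053
        assert abs(rate - 0.05) < 0.055

    def test_power_increases_with_slope(self, rng):
        n_trials, n_sub = 60, 120
        t = np.arange(1, n_trials + 1)
        rates = []
        null = simulate_null_slopes(n_trials, n_agents=400, seed=55)
        thresh = np.quantile(null.slopes[np.isfinite(null.slopes)], 0.95)
        for b in (0.0, 0.05, 0.15):
            p = 1 / (1 + np.exp(-(-1.5 + b * t)))
            Y = (rng.random((n_sub, n_trials)) < p).astype(float)
            s = batch_logistic_slopes(Y)
            rates.append(np.mean(s[np.isfinite(s)] > thresh))
        assert rates[0] < rates[1] < rates[2]
        assert rates[2] > 0.9
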