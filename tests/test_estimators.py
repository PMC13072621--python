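"""ATE estimators: hand arithmetic, algebraic identities and MC oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppct import (GaussianRegime, PpctConfig, PrognosticScoreSet,
                  TrajectoryParams, TrialScenario, aipw_ate,
                  aipw_from_predictions, ancova_ate, difference_in_means,
                  generate_gaussian_regime, generate_trial, haipw_ate,
                  lambda_star, naive_ate, normal_ci, permutation_test,
                  ppct_ate, ppi_ate, ppi_variance, rectifier)
from conftest import make_trial


class TestDifferenceInMeans:
    def test_hand_arithmetic(self):
        est = difference_in_means(make_trial([0, 1, 2], [1, 2, 3]))
        assert est.estimate == pytest.approx(1.0)
        assert est.variance == pytest.approx(1 / 3 + 1 / 3)

    def test_identical_arms_give_zero(self):
        est = difference_in_means(make_trial([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]))
        assert est.estimate == pytest.approx(0.0)


class TestNormalCi:
    def test_degenerate_interval_at_zero_variance(self):
        assert normal_ci(1.5, 0.0) == (1.5, 1.5)

    def test_level_validation(self):
        with pytest.raises(ValueError):
            normal_ci(0.0, 1.0, level=1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(var=st.floats(1e-6, 1e3), est=st.floats(-10, 10))
    def test_width_scales_as_root_variance(self, var, est):
        lo1, hi1 = normal_ci(est, var)
        lo4, hi4 = normal_ci(est, 4 * var)
        assert (hi4 - lo4) == pytest.approx(2 * (hi1 - lo1), rel=1e-9)


class TestNaiveAndRectifier:
    def test_mean_cancellation(self):
        trial, f = make_trial([0, 0], [2, 2], f0=[5, 5], f1=[1, 3])
        assert naive_ate(trial, f) == pytest.approx(0.0)

    def test_perfect_treated_predictions(self):
        trial, f = make_trial([0, 1], [2, 3], f0=[9, 9], f1=[2, 3])
        assert naive_ate(trial, f) == pytest.approx(0.0)

    def test_rectifier_hand_values(self):
        trial, f = make_trial([1, 1], [5, 5], f0=[0, 0], f1=[0, 0])
        assert rectifier(trial, f) == pytest.approx(1.0)
        trial2, f2 = make_trial([1.5, 2.5], [0, 0], f0=[1.5, 2.5], f1=[0, 0])
        assert rectifier(trial2, f2) == pytest.approx(0.0)

    def test_rectifier_absorbs_placebo_effect(self):
        """With an unbiased model, the rectifier averages to the
        arm-independent placebo shift over replicate trials."""
        placebo = 0.8
        # interior regime: moderate heterogeneity and mid-scale entry keep
        # the bounded score away from its floor/ceiling, where the oracle holds
        params = dataclasses.replace(TrajectoryParams(), shift_sd=4.0,
                                     log_accel_sd=0.4)
        rng = np.random.default_rng(5)
        vals = []
        for r in range(600):
            scenario = TrialScenario(placebo_effect=placebo, seed=40_000 + r,
                                     entry_age_mean=45.0, entry_age_sd=2.0)
            trial = generate_trial(scenario, params)
            truth = trial.ground_truth["true_untreated_progression"].to_numpy()
            f = truth + rng.normal(0, 0.3, len(truth))
            vals.append(rectifier(trial, f))
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(placebo, abs=3 * mc_se)

    def test_naive_ate_carries_prediction_bias(self):
        """A systematic prediction bias b shifts the naive ATE by -b."""
        bias = 1.2
        params = dataclasses.replace(TrajectoryParams(), shift_sd=4.0,
                                     log_accel_sd=0.4)
        rng = np.random.default_rng(6)
        vals = []
        for r in range(600):
            scenario = TrialScenario(seed=50_000 + r, entry_age_mean=45.0,
                                     entry_age_sd=2.0)
            trial = generate_trial(scenario, params)
            truth = trial.ground_truth["true_untreated_progression"].to_numpy()
            f = truth + bias + rng.normal(0, 0.3, len(truth))
            vals.append(naive_ate(trial, f))
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(-bias, abs=3 * mc_se + 0.05)


class TestLambdaStar:
    def test_perfect_prediction_limit(self, gaussian_trial):
        trial, scores = gaussian_trial(rho=0.999, n=5000, m=5000, seed=3)
        assert lambda_star(trial, scores) == pytest.approx(1.0, abs=0.05)

    def test_zero_variance_scores_rejected(self):
        trial, f = make_trial([0, 1, 2], [1, 2, 3], f0=[1, 1, 1], f1=[1, 1, 1])
        with pytest.raises(ValueError, match="zero variance"):
            lambda_star(trial, f)

    def test_matches_grid_search_argmin(self, gaussian_trial):
        grid = np.arange(-3.0, 3.0, 1e-4)
        for s in range(20):
            trial, scores = gaussian_trial(rho=0.5, n=15, m=12, seed=200 + s)
            f = scores.aligned_with(trial)
            closed = lambda_star(trial, scores)
            values = ppi_variance(trial, f, grid)
            assert closed == pytest.approx(grid[np.argmin(values)], abs=1e-3)


class TestPpct:
    def test_lambda_zero_is_bitwise_difference_in_means(self, gaussian_trial):
        trial, scores = gaussian_trial(rho=0.6, n=23, m=22, seed=1)
        classic = difference_in_means(trial)
        ppct = ppct_ate(trial, scores, PpctConfig(lambda_mode="fixed",
                                                  lambda_value=0.0))
        assert ppct.estimate == classic.estimate
        assert ppct.variance == classic.variance

    def test_zero_scores_make_ppi_equal_classic(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.4, n=30, m=30, seed=2)
        est = ppi_ate(trial, np.zeros(trial.n_total))
        assert est.estimate == difference_in_means(trial).estimate

    def test_constant_scores_reduce_to_classic(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.4, n=30, m=30, seed=12)
        est = ppct_ate(trial, np.full(trial.n_total, 7.0),
                       PpctConfig(lambda_mode="fixed", lambda_value=2.5))
        assert est.estimate == pytest.approx(
            difference_in_means(trial).estimate, abs=1e-12)

    def test_ppi_unbiased_under_null(self, gaussian_trial):
        ests = [ppi_ate(*gaussian_trial(rho=0.6, n=40, m=40, seed=s)).estimate
                for s in range(2000)]
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * mc_se

    def test_plugin_variance_never_exceeds_classic(self, gaussian_trial):
        for s in range(100):
            trial, scores = gaussian_trial(rho=0.3 + 0.005 * s,
                                           n=10 + s % 17, m=8 + s % 13, seed=s)
            assert (ppct_ate(trial, scores).variance
                    <= difference_in_means(trial).variance)

    def test_cross_fit_mode_runs_and_reports_fold_average(self, gaussian_trial):
        trial, scores = gaussian_trial(rho=0.6, n=23, m=22, seed=4)
        est = ppct_ate(trial, scores, PpctConfig(lambda_mode="cross_fit",
                                                 k_folds=5, seed=9))
        assert est.extras["lambda_mode"] == "cross_fit"
        assert np.isfinite(est.lam)
        est2 = ppct_ate(trial, scores, PpctConfig(lambda_mode="cross_fit",
                                                  k_folds=5, seed=9))
        assert est.estimate == est2.estimate  # seeded folds are reproducible


class TestAncova:
    def test_perfect_covariate_kills_variance(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.4, n=50, m=50, seed=5)
        est = ancova_ate(trial, trial.outcome.copy())
        assert est.variance == pytest.approx(0.0, abs=1e-12)

    def test_constant_covariate_rejected(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.4, n=20, m=20, seed=6)
        with pytest.raises(ValueError, match="constant"):
            ancova_ate(trial, np.ones(trial.n_total))

    def test_uninformative_covariate_matches_classic_variance(self, gaussian_trial):
        trial, scores = gaussian_trial(rho=0.0, n=20_000, m=20_000, seed=7)
        est = ancova_ate(trial, scores)
        assert est.variance == pytest.approx(
            difference_in_means(trial).variance, rel=0.02)

    def test_plugin_asymptotic_agrees_with_sandwich(self, gaussian_trial):
        """Equal-SD regime at n = m = 10^4: the pi-weighted plug-in form and
        the HC1 sandwich agree within 3%."""
        trial, scores = gaussian_trial(rho=0.6, n=10_000, m=10_000, seed=8)
        est = ancova_ate(trial, scores)
        comp = est.extras["components"]
        assert comp.eq_variance == pytest.approx(comp.sandwich_variance, rel=0.03)
        assert comp.pi0 + comp.pi1 == pytest.approx(1.0)


class TestAipw:
    def test_zero_outcome_model_reduces_to_horvitz_thompson(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.4, n=25, m=25, seed=9)
        zeros = np.zeros(trial.n_total)
        est = aipw_from_predictions(trial, zeros, zeros)
        assert est.estimate == pytest.approx(
            difference_in_means(trial).estimate, abs=1e-12)

    def test_propensity_validation(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.4, n=10, m=10, seed=10)
        zeros = np.zeros(trial.n_total)
        with pytest.raises(ValueError, match="propensity"):
            aipw_from_predictions(trial, zeros, zeros, propensity=1.0)

    def test_predictive_covariate_shrinks_variance(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.7, n=2000, m=2000, seed=11)
        est = aipw_ate(trial, seed=0)
        assert est.variance < difference_in_means(trial).variance


class TestHaipw:
    def test_empty_external_list_rejected(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.4, n=10, m=10, seed=12)
        with pytest.raises(ValueError):
            haipw_ate(trial, [])

    def test_useless_external_model_defers_to_aipw(self):
        """Pure-noise external scores get near-zero weight at large n."""
        regime = GaussianRegime(rho0=0.6, rho1=0.6, n=2000, m=2000)
        trial, _ = generate_gaussian_regime(regime, seed=13)
        rng = np.random.default_rng(0)
        noise_scores = rng.normal(0, 1, trial.n_total)
        est = haipw_ate(trial, [noise_scores], seed=0)
        aipw = aipw_ate(trial, seed=0)
        assert est.extras["weights"][0] > 0.9
        assert est.estimate == pytest.approx(aipw.estimate, abs=0.05)

    def test_informative_external_model_never_hurts(self, gaussian_trial):
        trial, scores = gaussian_trial(rho=0.7, n=1000, m=1000, seed=14)
        est = haipw_ate(trial, [scores], seed=0)
        aipw = aipw_ate(trial, seed=0)
        assert est.variance <= aipw.variance * (1 + 1e-6)

    def test_duplicate_external_sets_are_equivalent(self, gaussian_trial):
        trial, scores = gaussian_trial(rho=0.6, n=60, m=60, seed=15)
        one = haipw_ate(trial, [scores], seed=0)
        two = haipw_ate(trial, [scores, scores], seed=0)
        assert two.estimate == pytest.approx(one.estimate, abs=1e-6)
        assert two.variance == pytest.approx(one.variance, rel=1e-4)

    def test_constant_external_scores_match_classic(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.0, n=500, m=500, seed=16)
        est = haipw_ate(trial, [np.full(trial.n_total, 3.0)], seed=0)
        classic = difference_in_means(trial)
        assert est.estimate == pytest.approx(classic.estimate, abs=0.05)


class TestPermutation:
    def test_separated_arms_hit_resolution_floor(self):
        rng = np.random.default_rng(3)
        trial = make_trial(rng.normal(0, 0.1, 10), rng.normal(8, 0.1, 10))
        res = permutation_test(trial, difference_in_means, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_seeded_reproducibility(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.3, n=15, m=15, seed=17)
        a = permutation_test(trial, difference_in_means, n_perm=300, seed=5)
        b = permutation_test(trial, difference_in_means, n_perm=300, seed=5)
        assert a.p_value == b.p_value

    def test_null_p_values_are_uniform(self):
        """Exchangeable null: permutation p-values are ~U(0,1) (KS check)."""
        from scipy import stats

        ps = []
        for s in range(150):
            trial, _ = generate_gaussian_regime(
                GaussianRegime(rho0=0.0, rho1=0.0, n=12, m=12), seed=s)
            ps.append(permutation_test(trial, difference_in_means,
                                       n_perm=199, seed=s).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_permutation_count_rejected(self, gaussian_trial):
        trial, _ = gaussian_trial(rho=0.3, n=10, m=10, seed=18)
        with pytest.raises(ValueError):
            permutation_test(trial, difference_in_means, n_perm=50)
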