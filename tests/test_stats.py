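"""Logistic validation statistics and the simulated observer."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hazvis.exceptions import DegenerateDesignError, InvalidInputError
from hazvis.reference import GROUP_PARAMS, low_vision_observers
from hazvis.stats import (
    bin_trials,
    chow_test,
    fit_logistic,
    log_likelihood,
    lr_test_vs_null,
    predicted_probability,
    sample_hvs_distribution,
    simulate_observer,
    slope_vs_vision_regression,
)


def _simulate(rng, n, slope, intercept, guess=0.0):
    x = sample_hvs_distribution(n, rng)
    return simulate_observer(x, slope, intercept, guess, seed=rng)


class TestFitLogistic:
    def test_agrees_with_brute_force_likelihood(self, rng):
        """On a small dataset the IRLS fit matches an independent
        grid-search maximizer of the Bernoulli log-likelihood to 3 dp."""
        x = rng.uniform(0, 1, 20)
        y = (rng.random(20) < expit(2.5 * x - 1.0)).astype(int)
        trials = pd.DataFrame({"hvs": x, "correct": y})
        fit = fit_logistic(trials)
        # coarse-to-fine grid search, independent of IRLS
        a_lo, a_hi, b_lo, b_hi = -20.0, 20.0, -20.0, 20.0
        best = None
        for _ in range(6):
            aa = np.linspace(a_lo, a_hi, 41)
            bb = np.linspace(b_lo, b_hi, 41)
            ll = np.array([[log_likelihood(trials, a, b) for b in bb] for a in aa])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            best = (aa[i], bb[j])
            da, db = aa[1] - aa[0], bb[1] - bb[0]
            a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
            b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
        assert fit.slope == pytest.approx(best[0], abs=1e-3)
        assert fit.intercept == pytest.approx(best[1], abs=1e-3)

    def test_constant_predictor_rejected(self):
        trials = pd.DataFrame({"hvs": [0.5] * 10, "correct": [0, 1] * 5})
        with pytest.raises(DegenerateDesignError):
            fit_logistic(trials)

    def test_single_class_rejected(self):
        trials = pd.DataFrame({"hvs": np.linspace(0, 1, 10), "correct": [1] * 10})
        with pytest.raises(DegenerateDesignError):
            fit_logistic(trials)

    def test_separation_flagged(self):
        x = np.linspace(0, 1, 40)
        y = (x > 0.5).astype(int)
        fit = fit_logistic(pd.DataFrame({"hvs": x, "correct": y}))
        assert not fit.converged
        assert "separation" in fit.diagnostic

    def test_slope_recovery_coverage(self):
        """The 95% Wald CI covers the generating slope in >= 93% of
        replicate fits at the pooled-group sample size (A=3, B=-1,
        n=1750)."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            trials = _simulate(rng, 1750, 3.0, -1.0)
            fit = fit_logistic(trials)
            hits += fit.slope_ci[0] <= 3.0 <= fit.slope_ci[1]
        assert hits / n_rep >= 0.93

    def test_deviance_inequality(self, rng):
        for _ in range(20):
            trials = _simulate(rng, 200, rng.uniform(-4, 4), rng.uniform(-2, 2))
            try:
                fit = fit_logistic(trials)
            except DegenerateDesignError:
                continue
            assert fit.residual_deviance <= fit.null_deviance + 1e-8
            assert 0.0 <= fit.reduced_deviance_ratio <= 1.0


class TestPredictedProbability:
    def test_midpoint(self):
        fit = fit_logistic(
            pd.DataFrame({"hvs": [0, 0.2, 0.5, 0.9, 1.0], "correct": [0, 0, 1, 1, 0]})
        )
        x_mid = -fit.intercept / fit.slope
        assert predicted_probability(fit, x_mid) == pytest.approx(0.5)

    def test_strictly_increasing_for_positive_slope(self, rng):
        trials = _simulate(rng, 500, 3.0, -1.0)
        fit = fit_logistic(trials)
        assert fit.slope > 0
        x = np.linspace(0, 1, 50)
        p = predicted_probability(fit, x)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))


class TestLRTest:
    def test_statistic_is_deviance_drop_and_2loglik(self, rng):
        trials = _simulate(rng, 300, 2.0, -0.5)
        fit = fit_logistic(trials)
        stat, df, p = lr_test_vs_null(fit)
        assert df == 1
        # identity: deviance drop = 2 * (loglik_fit - loglik_null)
        x, y = trials["hvs"].to_numpy(), trials["correct"].to_numpy()
        p0 = y.mean()
        ll_null = np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0))
        ll_fit = log_likelihood(trials, fit.slope, fit.intercept)
        assert stat == pytest.approx(2 * (ll_fit - ll_null), rel=1e-6)

    def test_null_fit_gives_p_one(self):
        # a fit with no deviance reduction
        from hazvis.stats import LogisticFit

        fit = LogisticFit(0.0, 0.0, (0, 0), 100.0, 100.0, 50)
        stat, _, p = lr_test_vs_null(fit)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        """Under a zero-slope observer the LR test rejects at about the
        nominal 5% rate."""
        rng = np.random.default_rng(17)
        n_rep, rejections = 400, 0
        for _ in range(n_rep):
            trials = _simulate(rng, 200, 0.0, 0.3)
            try:
                fit = fit_logistic(trials)
            except DegenerateDesignError:
                n_rep -= 1
                continue
            _, _, p = lr_test_vs_null(fit)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


class TestChow:
    def test_df_at_group_sizes(self, rng):
        """Two groups of 1750 trials give df = (2, 3496)."""
        t1 = _simulate(rng, 1750, 3.02, -1.0)
        t2 = _simulate(rng, 1750, 1.54, -1.0)
        res = chow_test(t1, t2)
        assert res.df == (2, 3496)

    def test_null_split_rarely_rejects(self):
        """Randomly splitting one homogeneous sample: p > 0.05 in >= 90%
        of seeds."""
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            trials = _simulate(rng, 1000, 2.5, -1.0)
            half = trials.sample(frac=0.5, random_state=seed)
            rest = trials.drop(half.index)
            ok += chow_test(half, rest).p_value > 0.05
        assert ok / n_seeds >= 0.9

    def test_power_at_reported_group_slopes(self):
        """Samples generated at the two blur groups' slopes (3.02 vs 1.54,
        n = 1750 each) are detected as different at alpha = .001."""
        rejections = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            t1 = _simulate(rng, 1750, 3.02, -1.0)
            t2 = _simulate(rng, 1750, 1.54, -1.0)
            rejections += chow_test(t1, t2).p_value < 0.001
        assert rejections >= int(0.95 * n_seeds)

    def test_pearson_variant_runs(self, rng):
        t1 = _simulate(rng, 400, 3.0, -1.0)
        t2 = _simulate(rng, 400, 1.0, -1.0)
        res = chow_test(t1, t2, method="pearson")
        assert res.f_statistic >= 0
        assert res.df == (2, 796)

    def test_too_small_rejected(self, rng):
        tiny = _simulate(rng, 2, 1.0, 0.0)
        with pytest.raises(DegenerateDesignError):
            chow_test(tiny, tiny)


class TestBinTrials:
    def test_all_in_first_bin(self):
        t = pd.DataFrame({"hvs": [0.05] * 7, "correct": [1] * 7})
        bins = bin_trials(t)
        assert bins.loc[0, "correct"] == 7
        assert bins["correct"].sum() + bins["incorrect"].sum() == 7

    def test_exact_one_goes_to_last_bin(self):
        t = pd.DataFrame({"hvs": [1.0, 0.95], "correct": [1, 0]})
        bins = bin_trials(t)
        assert bins.iloc[-1]["correct"] == 1
        assert bins.iloc[-1]["incorrect"] == 1

    def test_counts_conserved(self, rng):
        x = rng.uniform(0, 1, 500)
        t = pd.DataFrame({"hvs": x, "correct": rng.integers(0, 2, 500)})
        bins = bin_trials(t)
        assert bins["correct"].sum() + bins["incorrect"].sum() == 500
        assert len(bins) == 10

    def test_bad_width_rejected(self):
        with pytest.raises(InvalidInputError):
            bin_trials(pd.DataFrame({"hvs": [0.5], "correct": [1]}), bin_width=0.3)


class TestSlopeVsVision:
    def test_reference_meta_regression_acuity(self):
        """The ten-observer reference table: slope of individual logistic
        slopes on acuity is -6.25 with R^2 = 0.35."""
        table = low_vision_observers()
        fit = slope_vs_vision_regression(table["slope"], table["acuity"])
        assert round(fit.slope, 2) == pytest.approx(-6.25)
        assert round(fit.r_squared, 2) == pytest.approx(0.35)

    def test_reference_meta_regression_cs(self):
        table = low_vision_observers()
        fit = slope_vs_vision_regression(table["slope"], table["cs"])
        assert round(fit.slope, 2) == pytest.approx(4.12)
        assert round(fit.r_squared, 2) == pytest.approx(0.56)

    def test_constant_slopes_give_zero(self):
        fit = slope_vs_vision_regression([2.0, 2.0, 2.0], [0.5, 1.0, 1.5])
        assert fit.slope == pytest.approx(0.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            slope_vs_vision_regression([1, 2, 3], [1.0, 1.0, 1.0])


class TestSimulateObserver:
    def test_accuracy_matches_logistic_intercept(self):
        """With zero slope, empirical accuracy converges to
        logistic(B)."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 10_000)
        t = simulate_observer(x, 0.0, -0.7, seed=42)
        expected = expit(-0.7)
        assert t["correct"].mean() == pytest.approx(expected, abs=0.015)

    def test_guessing_floor(self):
        x = np.zeros(10_000)
        t = simulate_observer(x, 40.0, -1000.0, guess_floor=0.2, seed=7)
        assert t["correct"].mean() == pytest.approx(0.2, abs=0.015)

    def test_seed_determinism(self):
        x = np.linspace(0, 1, 100)
        t1 = simulate_observer(x, 3.0, -1.0, seed=3)
        t2 = simulate_observer(x, 3.0, -1.0, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_bad_floor_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_observer([0.5], 1.0, 0.0, guess_floor=1.0)


class TestParameterRecovery:
    def test_median_slope_within_15_percent(self):
        """Across the slope range seen in the per-observer fits
        (A in {1.5, 3.0, 5.5}), the median recovered slope at both the
        per-subject (250) and pooled (1750) sample sizes is within 15% of
        truth."""
        rng = np.random.default_rng(23)
        for a_true, b_true, n in itertools.product(
            (1.5, 3.0, 5.5), (-2.0, 0.0), (250, 1750)
        ):
            recovered = []
            for _ in range(11):
                trials = _simulate(rng, n, a_true, b_true)
                recovered.append(fit_logistic(trials).slope)
            med = float(np.median(recovered))
            assert med == pytest.approx(a_true, rel=0.15), (a_true, b_true, n, med)

    def test_deviance_ratio_grows_with_effect_size(self):
        """The reduced deviance ratio increases with the true slope, on
        average."""
        rng = np.random.default_rng(31)
        means = []
        for a_true in (0.5, 2.0, 5.0):
            ratios = [
                fit_logistic(_simulate(rng, 500, a_true, -1.0)).reduced_deviance_ratio
                for _ in range(10)
            ]
            means.append(np.mean(ratios))
        assert means[0] < means[1] < means[2]

    def test_group_simulation_defaults_match_reference(self):
        """The bundled group parameters used by the experiment simulator
        agree with the reference table they summarize."""
        table = low_vision_observers()
        assert GROUP_PARAMS["low-vision"]["acuity"] == pytest.approx(
            table["acuity"].mean(), abs=0.01
        )
        assert GROUP_PARAMS["severe"]["cs"] == pytest.approx(
            round(1.72 - 0.69 * GROUP_PARAMS["severe"]["acuity"], 1), abs=0.005
        )
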