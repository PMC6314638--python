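import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromemo import simulate
from chromemo.circstats import wrap_angle
from chromemo.errormodel import (
    cohort_bias_test,
    eval_trig,
    fit_coefficients,
    fit_variance_profile,
    model_p_value,
    select_order,
)

from conftest import player_summaries


class TestEvalTrig:
    def test_zero_coefficients(self):
        t = np.linspace(-np.pi, np.pi, 17)
        assert np.allclose(eval_trig(np.zeros(7), 3, t), 0.0)

    def test_constant_only(self):
        t = np.linspace(-np.pi, np.pi, 17)
        assert np.allclose(eval_trig(np.array([0.5]), 0, t), 0.5)

    def test_matches_naive_summation(self):
        rng = np.random.default_rng(0)
        m = 12
        q = rng.normal(0, 0.2, 2 * m + 1)
        for t in rng.uniform(-np.pi, np.pi, 100):
            naive = q[0]
            for j in range(1, m + 1):
                naive += q[2 * j - 1] * math.sin(j * t)
                naive += q[2 * j] * math.cos(j * t)
            assert eval_trig(q, m, t) == pytest.approx(naive, abs=1e-12)

    def test_periodic(self):
        q = np.array([0.1, -0.2, 0.3])
        assert eval_trig(q, 1, 0.4) == pytest.approx(
            eval_trig(q, 1, 0.4 + 2 * np.pi))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            eval_trig(np.zeros(4), 2, 0.0)


class TestFitCoefficients:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(1)
        m = 3
        q_true = rng.normal(0, 0.1, 2 * m + 1)
        t = simulate.default_targets(32)
        y = eval_trig(q_true, m, t)
        fit = fit_coefficients(t, y, np.full(32, 0.02), m)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(fit.q, q_true, atol=1e-10)

    def test_matches_gls_oracle_five_points(self):
        # brute-force generalized least squares via explicit normal equations
        t = np.array([-2.0, -1.0, 0.3, 1.1, 2.7])
        y = np.array([0.1, -0.2, 0.05, 0.3, -0.1])
        w = np.array([0.1, 0.2, 0.05, 0.15, 0.1])
        m = 1
        X = np.column_stack([np.ones(5), np.sin(t), np.cos(t)])
        W = np.diag(1.0 / w**2)
        cov_oracle = np.linalg.inv(X.T @ W @ X)
        q_oracle = cov_oracle @ X.T @ W @ y
        fit = fit_coefficients(t, y, w, m, wrap_residuals=False)
        assert np.allclose(fit.q, q_oracle, atol=1e-10)
        assert np.allclose(fit.C, cov_oracle, atol=1e-10)

    def test_linearity_in_data(self):
        rng = np.random.default_rng(2)
        t = simulate.default_targets(32)
        y = rng.normal(0, 0.1, 32)
        w = np.full(32, 0.03)
        q1 = fit_coefficients(t, y, w, 4, wrap_residuals=False).q
        q2 = fit_coefficients(t, 2 * y, w, 4, wrap_residuals=False).q
        assert np.allclose(q2, 2 * q1)

    def test_chi2_nonincreasing_in_m(self):
        rng = np.random.default_rng(3)
        t = simulate.default_targets(32)
        y = rng.normal(0, 0.1, 32)
        w = np.full(32, 0.03)
        chi2s = [fit_coefficients(t, y, w, m).chi2 for m in range(2, 13)]
        assert np.all(np.diff(chi2s) <= 1e-9)

    def test_rank_deficient_raises(self):
        t = simulate.default_targets(8)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_coefficients(t, np.zeros(8), np.ones(8), 5)

    def test_covariance_psd_symmetric(self):
        rng = np.random.default_rng(4)
        t = simulate.default_targets(32)
        fit = fit_coefficients(t, rng.normal(0, 0.1, 32),
                               np.full(32, 0.05), 5)
        assert np.allclose(fit.C, fit.C.T)
        assert np.min(np.linalg.eigvalsh(fit.C)) > 0

    def test_parameter_recovery_two_se(self):
        # generate-and-refit: most coefficients should be within 2 SE
        rng = np.random.default_rng(5)
        m = 5
        q_true = np.zeros(2 * m + 1)
        q_true[1] = 0.25  # a1
        q_true[4] = 0.05  # b2
        q_true[9] = 0.03  # a5
        targets = simulate.default_targets(32)
        hits, total = 0, 0
        for rep in range(20):
            profile = simulate.make_trig_profile(q_true, sigma0=0.17)
            rs = simulate.simulate_responses(profile, targets, 20, seed=100 + rep)
            t, y, w, _ = player_summaries(rs)
            fit = fit_coefficients(t, y, w, m)
            hits += int(np.sum(np.abs(fit.q - q_true) <= 2 * fit.se))
            total += 2 * m + 1
        assert hits / total >= 0.90


class TestModelPValue:
    def test_chi2_zero_gives_one(self):
        assert model_p_value(0.0, 23) == pytest.approx(1.0)

    def test_matches_series_oracle(self):
        # upper regularized incomplete gamma via its power series, written
        # out independently of scipy
        def upper_tail(chi2, dof):
            a, x = dof / 2.0, chi2 / 2.0
            term = math.exp(-x + a * math.log(x) - math.lgamma(a + 1.0))
            total, k = term, 0
            while term > 1e-18 * total:
                k += 1
                term *= x / (a + k)
                total += term
            return 1.0 - total  # lower regularized gamma -> survival
        assert model_p_value(27.0, 23) == pytest.approx(
            upper_tail(27.0, 23), abs=1e-10)

    def test_monte_carlo_tail(self):
        rng = np.random.default_rng(6)
        draws = np.sum(rng.standard_normal((100_000, 23)) ** 2, axis=1)
        p_mc = np.mean(draws >= 27.0)
        se = np.sqrt(p_mc * (1 - p_mc) / len(draws))
        assert abs(model_p_value(27.0, 23) - p_mc) <= 3 * se

    def test_monotone_in_chi2(self):
        ps = [model_p_value(c, 23) for c in np.linspace(0, 80, 30)]
        assert np.all(np.diff(ps) < 0)

    def test_dof_validation(self):
        with pytest.raises(ValueError):
            model_p_value(1.0, 0)


class TestSelectOrder:
    def test_noiseless_true_order_selected(self):
        rng = np.random.default_rng(7)
        m = 3
        q_true = rng.normal(0, 0.1, 2 * m + 1)
        t = simulate.default_targets(32)
        y = eval_trig(q_true, m, t)
        fit = select_order(t, y, np.full(32, 0.02))
        assert fit.m == 3
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_recovers_order_neighborhood(self):
        # order-selection simulation: true m=5 with realistic noise
        q_true = np.zeros(11)
        q_true[1], q_true[8], q_true[9] = 0.2, 0.06, 0.08  # a1, b4, a5
        targets = simulate.default_targets(32)
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            profile = simulate.make_trig_profile(q_true, sigma0=0.15)
            rs = simulate.simulate_responses(profile, targets, 20, seed=rep)
            t, y, w, _ = player_summaries(rs)
            fit = select_order(t, y, w)
            hits += int(4 <= fit.m <= 7)
        assert hits / n_rep >= 0.80

    def test_scan_starts_at_two(self):
        rng = np.random.default_rng(8)
        t = simulate.default_targets(32)
        y = rng.normal(0, 0.05, 32)
        fit = select_order(t, y, np.full(32, 0.05))
        assert fit.m >= 2


class TestVarianceProfile:
    def test_constant_variance_recovered(self):
        profile = simulate.make_profile("unbiased", sigma0=0.2)
        rs = simulate.simulate_responses(profile, simulate.default_targets(32),
                                         50, seed=9)
        t, _, w, eps2 = player_summaries(rs)
        fit = fit_variance_profile(t, eps2, w)
        grid = np.linspace(-np.pi, np.pi, 256)
        assert np.all(np.abs(fit(grid) - 0.04) / 0.04 < 0.25)

    def test_equal_inputs_constant_fit(self):
        t = simulate.default_targets(32)
        eps2 = np.full(32, 0.03)
        fit = fit_variance_profile(t, eps2, np.full(32, 0.01))
        assert fit.q[0] == pytest.approx(0.03, abs=1e-9)
        assert np.allclose(fit.q[1:], 0.0, atol=1e-9)

    def test_positive_on_grid(self, null_responses):
        t, _, w, eps2 = player_summaries(null_responses)
        fit = fit_variance_profile(t, eps2, w)
        grid = np.linspace(-np.pi, np.pi, 1024, endpoint=False)
        assert np.all(fit(grid) > 0)


class TestCohortBias:
    def test_exact_targets_give_zero_statistic(self):
        import pandas as pd

        t = simulate.default_targets(32)
        summaries = pd.DataFrame({
            "player_id": "a", "target_index": np.arange(32), "target_rad": t,
            "n": 15, "mean_rad": t, "sd_rad": 0.17,
        })
        res = cohort_bias_test(summaries)
        assert res.per_player.iloc[0]["S"] == pytest.approx(0.0)
        assert not res.per_player.iloc[0]["reject"]

    def test_null_cohort_type_one_error(self):
        # the per-cell weights use the *estimated* SD, so each summand of S
        # is t-distributed rather than Gaussian; the statistic is slightly
        # inflated at small n and converges to chi-square as n grows
        cohort = simulate.make_null_cohort(60, 40, sigma0=0.17, seed=10)
        pvals = []
        for rs in cohort:
            res = cohort_bias_test(rs.summaries(), alpha=0.01)
            pvals.append(res.per_player.iloc[0]["p_value"])
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert frac <= 0.25  # ~0.08 expected at n=40, loose bound for 60 players

    def test_mixed_strategy_all_rejected(self):
        rng = np.random.default_rng(11)
        summaries = []
        for i in range(6):
            foci = np.sort(rng.uniform(-np.pi, np.pi, 4))
            profile = simulate.make_profile("mixed", sigma0=0.15,
                                            mixing_weight=0.3,
                                            focal_colors=foci)
            rs = simulate.simulate_responses(profile,
                                             simulate.default_targets(32),
                                             20, seed=200 + i,
                                             player_id=f"m{i}")
            summaries.append(rs.summaries())
        import pandas as pd

        res = cohort_bias_test(pd.concat(summaries, ignore_index=True))
        assert res.per_player["reject"].all()

    def test_per_target_ttests_present(self, null_responses):
        res = cohort_bias_test(null_responses.summaries())
        assert len(res.per_target) == 32
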