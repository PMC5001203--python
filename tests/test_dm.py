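"""Estimation and differential-methylation testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from mbdcapdm.counts import CountMatrix
from mbdcapdm.delaporte import DelaporteFit, delaporte_loglik_grad, delaporte_pmf
from mbdcapdm.dm import (
    adjusted_variance,
    bh_adjust,
    estimate_lambda,
    mle_estimate,
    moderated_fisher_test,
    np_estimate,
    run_dm,
    signal_moments,
    variance_trend,
)


class TestLambda:
    def test_arithmetic_mean(self):
        est = estimate_lambda(pd.DataFrame([[2.0, 4.0, 6.0]]))
        assert est.lam.iloc[0] == pytest.approx(4.0, abs=1e-9)
        assert est.m == 3

    def test_all_zero(self):
        est = estimate_lambda(pd.DataFrame([[0.0, 0.0, 0.0]]))
        assert est.lam.iloc[0] == 0.0

    def test_matches_mean_oracle(self, rng):
        b = pd.DataFrame(rng.poisson(9.0, size=(40, 5)).astype(float))
        est = estimate_lambda(b)
        assert np.allclose(est.lam, b.to_numpy().mean(axis=1), atol=1e-9)


class TestSignalMoments:
    def test_constant_inputs(self):
        mom = signal_moments(
            pd.DataFrame([[10, 10, 10]]), pd.DataFrame([[2, 2, 2]])
        ).iloc[0]
        assert mom.mu_s == 8.0
        assert mom.var_x == 0.0 and mom.var_b == 0.0
        assert mom.var_s == pytest.approx(1e-8)

    def test_background_exceeding_signal_clamps(self):
        mom = signal_moments(
            pd.DataFrame([[1, 2, 3]]), pd.DataFrame([[10, 11, 12]])
        ).iloc[0]
        assert mom.mu_s == 0.0 and mom.mu_clamped

    def test_uncorrelated_replicates_add_variances(self, rng):
        """With rho = 0 (m = 2 forces it), var_s = var_x + var_b."""
        x = pd.DataFrame(rng.poisson(50, size=(30, 2)).astype(float))
        b = pd.DataFrame(rng.poisson(5, size=(30, 2)).astype(float))
        mom = signal_moments(x, b)
        assert np.allclose(mom.var_s, mom.var_x + mom.var_b)
        assert (mom.rho == 0).all()

    def test_rho_clamped_to_unit_interval(self, rng):
        x = pd.DataFrame(rng.normal(100, 10, size=(200, 4)))
        b = pd.DataFrame(rng.normal(20, 5, size=(200, 4)))
        mom = signal_moments(x.clip(lower=0), b.clip(lower=0))
        assert (mom.rho >= 0).all() and (mom.rho <= 1).all()


class TestAdjustedVariance:
    def test_trend_recovers_quadratic_law(self, rng):
        """var(mu) = mu + 0.2 mu^2 recovered within 10% over central 90%."""
        n = 2000
        mu = rng.lognormal(np.log(200), 0.8, n)
        true_var = mu + 0.2 * mu**2
        var_obs = true_var * rng.chisquare(10, n) / 10
        v = variance_trend(mu, var_obs, df=10)
        lo, hi = np.quantile(mu, [0.05, 0.95])
        central = (mu >= lo) & (mu <= hi)
        ratio = v(mu[central]) / true_var[central]
        assert np.all(np.abs(np.log(ratio)) < np.log(1.10))

    def test_trend_conservative_lean_at_small_df(self, rng):
        """At df=2 the robust fit plus mean bias correction sits at or
        slightly above the generating law, never below it."""
        n = 2000
        mu = rng.lognormal(np.log(200), 0.8, n)
        true_var = 3.0 * mu
        var_obs = true_var * rng.chisquare(2, n) / 2
        v = variance_trend(mu, var_obs, df=2)
        lo, hi = np.quantile(mu, [0.05, 0.95])
        central = (mu >= lo) & (mu <= hi)
        ratio = v(mu[central]) / true_var[central]
        assert np.quantile(ratio, 0.05) > 0.85
        assert 1.0 <= np.median(ratio) < 1.35

    def test_moderation_pulls_toward_trend(self, rng):
        n = 1000
        mu = rng.lognormal(np.log(100), 0.5, n)
        true_var = 2.0 * mu
        var_obs = true_var * rng.chisquare(2, n) / 2
        adj = adjusted_variance(mu, var_obs, df=2)
        # squeezing reduces spread relative to the raw estimates
        assert np.var(np.log(adj / true_var)) < np.var(
            np.log(np.maximum(var_obs, 1e-8) / true_var)
        )
        assert np.all(adj > mu)

    def test_exceeds_mean_always(self, rng):
        mu = rng.uniform(0, 50, 300)
        var = rng.uniform(0, 10, 300)
        adj = adjusted_variance(mu, var, df=2)
        assert np.all(adj > mu)

    def test_small_cohort_fallback(self):
        mu = np.array([10.0, 20.0])
        var = np.array([30.0, 10.0])
        adj = adjusted_variance(mu, var, df=2)
        assert np.all(adj > mu)


class TestNPEstimate:
    def test_direct_substitution(self):
        fit = np_estimate(10.0, 20.0)
        assert fit.r == pytest.approx(10.0)
        assert fit.p == pytest.approx(0.5)

    def test_gamma_identities_on_random_moments(self, rng):
        for _ in range(30):
            mu = rng.uniform(1, 100)
            var = mu * rng.uniform(1.01, 5)
            fit = np_estimate(mu, var, lam=rng.uniform(0, 10))
            assert fit.alpha == fit.r
            assert abs(fit.p - 1.0 / (fit.beta + 1.0)) < 1e-9

    def test_poisson_limit_caps_r(self):
        fit = np_estimate(1000.0, 1000.0 + 1e-9)
        assert fit.r == pytest.approx(1e8)
        assert "r_capped" in fit.flags

    def test_zero_signal_degenerate(self):
        fit = np_estimate(0.0, 5.0, lam=3.0)
        assert fit.r == 0.0 and fit.p == 1.0 and fit.lam == 3.0
        assert "degenerate_signal" in fit.flags


def _delap_draw(rng, alpha, beta, lam, m):
    return rng.negative_binomial(alpha, 1 / (1 + beta), m) + rng.poisson(lam, m)


class TestMLE:
    def test_ascent_over_initializer(self, rng):
        x = _delap_draw(rng, 2.0, 1.5, 3.0, 30)
        b = rng.poisson(3.0, 30)
        init = DelaporteFit(r=1.0, p=0.5, lam=2.5)
        fit = mle_estimate(x, b, init=init)

        def loglik(f):
            ll = delaporte_loglik_grad(x, f.alpha, max(f.beta, 1e-9), max(f.lam, 1e-9))[0]
            ll += stats.poisson.logpmf(b, max(f.lam, 1e-9)).sum()
            return ll

        assert fit.loglik >= loglik(init) - 1e-6

    def test_zero_background_approaches_nb_mle(self, rng):
        """With b = 0 the fit collapses to (numerically) pure NB."""
        x = rng.negative_binomial(2.0, 1 / 2.5, 150)
        b = np.zeros(150)
        fit = mle_estimate(x, b)
        assert fit.lam < 0.05

        # independent NB-only MLE oracle
        def nb_negll(theta):
            r, p = np.exp(theta[0]), 1 / (1 + np.exp(theta[1]))
            return -stats.nbinom.logpmf(x, r, p).sum()

        res = optimize.minimize(nb_negll, [np.log(2), np.log(1.5)], method="Nelder-Mead")
        r_oracle = np.exp(res.x[0])
        assert fit.r == pytest.approx(r_oracle, rel=0.15)

    def test_all_zero_counts_degenerate(self):
        fit = mle_estimate(np.zeros(10), np.full(10, 2.0))
        assert fit.r == 0.0 and fit.lam == pytest.approx(2.0)
        assert "degenerate_signal" in fit.flags


class TestModeratedFisher:
    def test_empty_pool_gives_one(self):
        fa = DelaporteFit(r=1.0, p=0.5, lam=1.0)
        assert moderated_fisher_test(0, 0, fa, fa) == 1.0

    def test_modal_split_gives_one(self):
        """Symmetric fits with x = y at the modal pair return p = 1."""
        fa = DelaporteFit(r=4.0, p=0.5, lam=2.0)
        n = 12
        joint = np.array(
            [
                delaporte_pmf(a, fa.alpha, fa.beta, fa.lam)
                * delaporte_pmf(n - a, fa.alpha, fa.beta, fa.lam)
                for a in range(n + 1)
            ]
        )
        assert joint.argmax() == 6  # verify modality by enumeration
        assert moderated_fisher_test(6, 6, fa, fa) == pytest.approx(1.0)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(25):
            fa = DelaporteFit(
                r=rng.uniform(0.5, 10), p=rng.uniform(0.1, 0.9), lam=rng.uniform(0, 20)
            )
            fb = DelaporteFit(
                r=rng.uniform(0.5, 10), p=rng.uniform(0.1, 0.9), lam=rng.uniform(0, 20)
            )
            x, y = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            if x + y == 0:
                continue
            n = x + y
            pa = np.array([delaporte_pmf(a, fa.alpha, fa.beta, fa.lam) for a in range(n + 1)])
            pb = np.array([delaporte_pmf(bb, fb.alpha, fb.beta, fb.lam) for bb in range(n + 1)])
            joint = pa * pb[::-1]
            oracle = joint[joint <= joint[x] * (1 + 1e-7)].sum() / joint.sum()
            assert moderated_fisher_test(x, y, fa, fb) == pytest.approx(
                oracle, abs=1e-12
            )

    def test_enumeration_cap(self):
        fa = DelaporteFit(r=1.0, p=0.5, lam=1.0)
        with pytest.raises(ValueError, match="enumeration"):
            moderated_fisher_test(600000, 600001, fa, fa)

    def test_extreme_split_is_significant(self):
        fa = DelaporteFit(r=5.0, p=0.1, lam=10.0)
        p = moderated_fisher_test(180, 2, fa, fa)
        assert 0 < p < 1e-6


class TestBH:
    def test_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestRunDM:
    def _matrices(self, x, b, conditions):
        samples = [f"s{i}" for i in range(x.shape[1])]
        cond = pd.Series(list(conditions), index=samples)
        idx = [f"p{i}" for i in range(x.shape[0])]
        return (
            CountMatrix(pd.DataFrame(x, index=idx, columns=samples), cond),
            CountMatrix(pd.DataFrame(b, index=idx, columns=samples), cond),
        )

    def test_identical_conditions_not_significant(self, rng):
        n = 120
        base_x = rng.poisson(200, size=(n, 3))
        base_b = rng.poisson(20, size=(n, 3))
        x = np.hstack([base_x, base_x])
        b = np.hstack([base_b, base_b])
        pm, bm = self._matrices(x, b, "AAABBB")
        res = run_dm(pm, bm)
        assert (res["pvalue"] >= 0.99).all()

    def test_requires_two_conditions(self, rng):
        pm, bm = self._matrices(
            rng.poisson(50, (60, 3)), rng.poisson(5, (60, 3)), "AAA"
        )
        with pytest.raises(ValueError, match="two conditions"):
            run_dm(pm, bm)

    def test_requires_replicates(self, rng):
        pm, bm = self._matrices(
            rng.poisson(50, (60, 3)), rng.poisson(5, (60, 3)), "AAB"
        )
        with pytest.raises(ValueError, match="replicate"):
            run_dm(pm, bm)

    def test_promoters_without_background_excluded(self, rng):
        x = rng.poisson(100, size=(80, 4))
        b = rng.poisson(10, size=(80, 4))
        pm, bm = self._matrices(x, b, "AABB")
        bm.data = bm.data.iloc[:-5]
        res = run_dm(pm, bm)
        assert len(res) == 75
        assert len(res.attrs["excluded"]) == 5

    def test_strong_shift_detected_with_bh_monotone(self, rng):
        n = 200
        x_a = rng.poisson(100, size=(n, 3))
        x_b = rng.poisson(100, size=(n, 3))
        x_b[:10] = rng.poisson(500, size=(10, 3))  # strong DM block
        b = rng.poisson(10, size=(n, 6))
        pm, bm = self._matrices(np.hstack([x_a, x_b]), b, "AAABBB")
        res = run_dm(pm, bm)
        assert (res["pvalue"].iloc[:10] < 0.01).all()
        assert (res["log2fc"].iloc[:10] < -1).all()
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()
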