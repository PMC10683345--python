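"""Null model, pairwise likelihood, residual covariance, statistic, p-value."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, ndtri
from scipy.stats import chi2, multivariate_normal

import nrvat
from nrvat import core as c
from _oracle_utils import (covariance_zscores, empirical_residual_covariance,
                           simulate_setting1_batched, true_null_fit)
from conftest import singleton_pedigree

GAMMA = np.array([-2.0, 1.0, 1.0])


def _setting1_dataset(ped, h2, seed, gamma=GAMMA):
    rng = np.random.default_rng(seed)
    X = nrvat.simulate_covariates(ped, rng)
    mu = expit(X @ gamma)
    Y = simulate_setting1_batched(ped, mu, h2, 1, rng)[0]
    return Y.astype(float), X


class TestNullLogisticFit:
    def test_intercept_only_closed_forms(self):
        ped = singleton_pedigree(8)
        X = np.ones((8, 1))
        fit = c.fit_null_logistic(np.array([1, 0, 1, 0, 1, 0, 1, 0.0]), X, ped)
        assert fit.gamma[0] == pytest.approx(0.0, abs=1e-8)
        fit = c.fit_null_logistic(np.array([1, 0, 0, 0, 1, 0, 0, 0.0]), X, ped)
        assert fit.gamma[0] == pytest.approx(np.log(1 / 3), abs=1e-8)

    def test_matches_statsmodels(self, default_ped):
        import statsmodels.api as sm

        Y, X = _setting1_dataset(default_ped, 0.0, seed=31)
        fit = c.fit_null_logistic(Y, X, default_ped)
        ref = sm.GLM(Y, X, family=sm.families.Binomial()).fit(tol=1e-10)
        assert np.allclose(fit.gamma, ref.params, atol=1e-7)
        assert np.allclose(fit.mu, ref.fittedvalues, atol=1e-8)

    def test_consistency_at_large_n(self):
        """h2=0, N=6000: gamma_hat within 3 SE of (-2, 1, 1)."""
        import statsmodels.api as sm

        ped = nrvat.Pedigree([
            f for _ in range(10) for f in nrvat.default_pedigree_set().families
        ])
        # distinct family ids are irrelevant to the fit itself
        Y, X = _setting1_dataset(ped, 0.0, seed=32)
        fit = c.fit_null_logistic(Y, X, ped)
        se = sm.GLM(Y, X, family=sm.families.Binomial()).fit().bse
        assert np.all(np.abs(fit.gamma - GAMMA) < 3 * se)

    def test_perfect_separation_raises(self):
        ped = singleton_pedigree(20)
        x = np.linspace(-1, 1, 20)
        X = np.column_stack([np.ones(20), x])
        Y = (x > 0).astype(float)
        with pytest.raises(c.FitError):
            c.fit_null_logistic(Y, X, ped)

    def test_rank_deficient_design(self):
        ped = singleton_pedigree(10)
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            c.fit_null_logistic(np.tile([0, 1.0], 5), X, ped)

    def test_sandwich_blocks_shapes(self, default_ped):
        Y, X = _setting1_dataset(default_ped, 0.2, seed=33)
        fit = c.fit_null_logistic(Y, X, default_ped)
        assert fit.A.shape == (3, 3)
        assert np.all(np.linalg.eigvalsh(fit.A) > 0)
        assert fit.scores.shape == (120, 3)
        # score equations: family scores sum to ~0 at the optimum
        assert np.max(np.abs(fit.scores.sum(axis=0))) < 1e-6


class TestPairProb:
    def test_trivial_values(self):
        assert c.pair_prob(0.5, 0.5, 0.0) == pytest.approx(0.25, abs=1e-12)
        assert c.pair_prob(0.5, 0.5, 1 - 1e-9) == pytest.approx(0.5, abs=1e-4)
        assert c.pair_prob(0.3, 0.6, 0.0) == pytest.approx(0.18, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            c.pair_prob(0.5, 0.5, 1.0)
        with pytest.raises(ValueError):
            c.pair_prob(0.0, 0.5, 0.2)

    def test_monte_carlo_orthant_oracle(self):
        """mu=0.3, mu'=0.6, rho=0.4 vs 10^7 bivariate-normal draws."""
        rng = np.random.default_rng(777)
        rho, n_total = 0.4, 10_000_000
        za, zb = ndtri(0.3), ndtri(0.6)
        hits = 0
        for _ in range(10):
            z1 = rng.standard_normal(n_total // 10)
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_total // 10)
            hits += int(((z1 < za) & (z2 < zb)).sum())
        phat = hits / n_total
        se = np.sqrt(phat * (1 - phat) / n_total)
        assert abs(float(c.pair_prob(0.3, 0.6, 0.4)) - phat) < 3 * se

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        h=st.floats(-3, 3), k=st.floats(-3, 3),
        rho=st.floats(-0.95, 0.95),
    )
    def test_agrees_with_scipy_bivariate_cdf(self, h, k, rho):
        ours = c.pair_prob(float(expit(h)), float(expit(k)), rho)
        mv = multivariate_normal(cov=[[1, rho], [rho, 1]])
        ref = mv.cdf([ndtri(expit(h)), ndtri(expit(k))])
        assert ours == pytest.approx(ref, abs=5e-6)


class TestEstimateH2:
    def test_no_pairs_raises(self):
        ped = singleton_pedigree(50)
        with pytest.raises(c.EstimationError):
            c.estimate_h2(np.zeros(50), np.full(50, 0.3), ped)

    def test_unrelated_pairs_return_zero_with_warning(self):
        fams = [nrvat.Family(f"U{i}", [nrvat.Individual("1"),
                                       nrvat.Individual("2")])
                for i in range(30)]
        ped = nrvat.Pedigree(fams)
        with pytest.warns(UserWarning, match="zero relatedness"):
            h2 = c.estimate_h2(np.tile([0, 1.0], 30), np.full(60, 0.3), ped)
        assert h2 == 0.0

    def test_null_recovery(self, default_ped):
        """h2=0 truth: boundary estimator piles up at 0 (median ~0, small mean)."""
        rng = np.random.default_rng(555)
        psis = default_ped.relatedness_blocks()
        h2s = []
        for _ in range(60):
            X = nrvat.simulate_covariates(default_ped, rng)
            mu = expit(X @ GAMMA)
            Y = simulate_setting1_batched(default_ped, mu, 0.0, 1, rng)[0]
            fit = c.fit_null_logistic(Y.astype(float), X, default_ped)
            h2s.append(c.estimate_h2(Y, fit.mu, default_ped, psis))
        h2s = np.array(h2s)
        assert np.median(h2s) <= 0.02
        assert h2s.mean() <= 0.1

    def test_recovery_at_half(self, default_ped):
        """h2=0.5 truth at I=120: unbiased within MC error over 40 replicates."""
        rng = np.random.default_rng(556)
        psis = default_ped.relatedness_blocks()
        h2s = []
        for _ in range(40):
            X = nrvat.simulate_covariates(default_ped, rng)
            mu = expit(X @ GAMMA)
            Y = simulate_setting1_batched(default_ped, mu, 0.5, 1, rng)[0]
            fit = c.fit_null_logistic(Y.astype(float), X, default_ped)
            h2s.append(c.estimate_h2(Y, fit.mu, default_ped, psis))
        assert abs(np.mean(h2s) - 0.5) < 0.1


class TestSigmaBlock:
    def test_independence_gives_diagonal(self):
        mu = np.array([0.2, 0.5, 0.7])
        sig = c.sigma_block(mu, np.eye(3))
        assert np.allclose(sig, np.diag(mu * (1 - mu)), atol=1e-12)

    def test_orthant_closed_form(self):
        """mu=mu'=0.5, rho=0.25: Sigma_jk = 1/4 + asin(rho)/2pi - 1/4 = 0.04015."""
        gam = np.array([[1.0, 0.25], [0.25, 1.0]])
        sig = c.sigma_block(np.array([0.5, 0.5]), gam)
        expected = np.arcsin(0.25) / (2 * np.pi)
        assert sig[0, 1] == pytest.approx(expected, abs=1e-9)
        assert sig[0, 1] == pytest.approx(0.04015, abs=1e-4)

    def test_matches_empirical_covariance(self, octet):
        """Sigma_i vs the residual covariance of 10^5 copula replicates."""
        ped1 = nrvat.Pedigree([octet])
        rng = np.random.default_rng(888)
        X = nrvat.simulate_covariates(ped1, rng)
        mu = expit(X @ GAMMA)
        Y = simulate_setting1_batched(ped1, mu, 0.5, 100_000, rng)
        emp = np.cov(Y.T.astype(float))
        psi = nrvat.relatedness(octet)
        sig = c.sigma_block(mu, nrvat.copula_correlation(psi, 0.5))
        z = covariance_zscores(emp, sig, 100_000)
        assert np.max(np.abs(z)) < 4.0


class TestOmega:
    def test_symmetric_and_reduces_to_sigma_at_large_i(self):
        """||Omega - Sigma|| = O(1/I): ratio falls ~4x per 4x more families."""
        rates = {}
        for reps in (1, 4, 16):  # I = 30, 120, 480
            ped = nrvat.default_pedigree_set(10 * reps, 10 * reps, 10 * reps)
            rng = np.random.default_rng(40 + reps)
            X = nrvat.simulate_covariates(ped, rng)
            fit = true_null_fit(ped, X, GAMMA)
            sig = c.sigma_blocks_for(fit, ped, 0.3)
            omega = c.build_omega(fit, sig, X, ped)
            assert np.array_equal(omega, omega.T)
            Sigma = np.zeros_like(omega)
            for sl, s in zip(ped.family_slices(), sig):
                Sigma[sl, sl] = s
            # per-entry corrections scale as 1/I; max-norm isolates that
            rates[reps] = (np.max(np.abs(omega - Sigma))
                           / np.max(np.abs(Sigma)))
        assert rates[1] > rates[4] > rates[16]
        assert rates[1] / rates[16] > 8  # expected ~16 for exact 1/I scaling

    def test_empirical_residual_covariance_keystone_small(self, default_ped):
        """Omega vs 4000-replicate empirical covariance (coarse screen; the
        full-scale run lives in the acceptance suite)."""
        rng = np.random.default_rng(999)
        X = nrvat.simulate_covariates(default_ped, rng)
        h2 = 0.5
        fit = true_null_fit(default_ped, X, GAMMA)
        sig = c.sigma_blocks_for(fit, default_ped, h2)
        omega = c.build_omega(fit, sig, X, default_ped)
        emp = empirical_residual_covariance(default_ped, X, GAMMA, h2, 4000, rng)
        z = covariance_zscores(emp, omega, 4000)
        assert (np.abs(z) > 4).mean() < 0.005

    def test_b_modes_agree_asymptotically(self, default_ped):
        Y, X = _setting1_dataset(default_ped, 0.2, seed=41)
        fit = c.fit_null_logistic(Y, X, default_ped)
        sig = c.sigma_blocks_for(fit, default_ped, 0.2)
        om_m = c.build_omega(fit, sig, X, default_ped, b_mode="model")
        om_e = c.build_omega(fit, sig, X, default_ped, b_mode="empirical")
        # the B estimators differ O_p(I^-1/2); blocks agree to leading order
        assert np.linalg.norm(om_m - om_e) / np.linalg.norm(om_m) < 0.05

    def test_unknown_b_mode(self, default_ped):
        Y, X = _setting1_dataset(default_ped, 0.2, seed=42)
        fit = c.fit_null_logistic(Y, X, default_ped)
        sig = c.sigma_blocks_for(fit, default_ped, 0.2)
        with pytest.raises(ValueError):
            c.build_omega(fit, sig, X, default_ped, b_mode="bogus")


class TestScoreStatistic:
    def test_trivial_cases(self):
        mu = np.full(4, 0.5)
        Q, _ = c.score_statistic(mu, mu, np.eye(4))  # zero residuals
        assert Q == 0.0
        Y = np.array([1, 0, 1, 0.0])
        Q, tr = c.score_statistic(Y, mu, np.eye(4))
        assert Q == pytest.approx(np.sum((Y - mu) ** 2))
        assert tr == pytest.approx(4 * 0.25)

    def test_hand_computed_toy(self):
        """K from G=[[1,0],[0,1],[2,0],[0,0]], w=1; e=(.5,-.5,.2,-.2) -> Q=1.06."""
        G = np.array([[1, 0], [0, 1], [2, 0], [0, 0]], dtype=float)
        K = G @ G.T
        mu = np.full(4, 0.5)
        Y = mu + np.array([0.5, -0.5, 0.2, -0.2])
        Q, _ = c.score_statistic(Y, mu, K)
        assert Q == pytest.approx(1.06, abs=1e-12)


class TestMixturePvalue:
    def test_chi2_1_quantile(self):
        p, _ = c.mixture_chisq_sf(chi2.isf(0.05, 1), np.array([1.0]))
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_equal_weights_scaled_chi2(self):
        m, cc = 7, 2.5
        q = cc * chi2.isf(0.2, m)
        p, _ = c.mixture_chisq_sf(q, np.full(m, cc))
        assert p == pytest.approx(0.2, abs=1e-6)

    def test_monte_carlo_mixture_oracle(self):
        """Random weights (length 10) vs a 10^6-draw mixture tail estimate."""
        rng = np.random.default_rng(2718)
        lam = rng.uniform(0.2, 3.0, 10)
        draws = (rng.standard_normal((1_000_000, 10)) ** 2) @ lam
        for prob in (0.5, 0.05, 0.005):
            q = np.quantile(draws, 1 - prob)
            mc = (draws > q).mean()
            se = np.sqrt(mc * (1 - mc) / 1_000_000)
            p, method = c.mixture_chisq_sf(q, lam)
            assert abs(p - mc) < 3 * se
            assert method == "imhof"

    def test_liu_close_to_imhof_in_bulk(self):
        rng = np.random.default_rng(3141)
        lam = rng.uniform(0.5, 2.0, 15)
        q = lam.sum() * 1.3
        p_i, _ = c._imhof_sf(q / lam.max(), lam / lam.max())
        p_l = c._liu_sf(q, lam)
        assert p_l == pytest.approx(p_i, abs=0.01)

    def test_monotone_decreasing_in_q(self):
        lam = np.array([3.0, 1.0, 0.5])
        ps = [c.mixture_chisq_sf(q, lam)[0] for q in np.linspace(0.1, 40, 25)]
        assert np.all(np.diff(ps) < 0)

    def test_eigen_route_equivalence(self, default_ped):
        """Nonzero eigenvalues of S K S equal those of K Omega (tol 1e-8)."""
        Y, X = _setting1_dataset(default_ped, 0.3, seed=51)
        fit = c.fit_null_logistic(Y, X, default_ped)
        sig = c.sigma_blocks_for(fit, default_ped, 0.3)
        omega = c.build_omega(fit, sig, X, default_ped)
        rng = np.random.default_rng(52)
        G = rng.integers(0, 3, size=(600, 6)).astype(float)
        K = G @ G.T
        _, theta, _ = c.pvalue_mixture_chisq(1.0, omega, K)
        ref = np.sort(np.real(np.linalg.eigvals(K @ omega)))[::-1][:len(theta)]
        scale = max(abs(ref).max(), 1.0)
        assert np.allclose(np.sort(theta), np.sort(ref), atol=1e-8 * scale)

    def test_theta_sum_equals_trace(self, default_ped):
        Y, X = _setting1_dataset(default_ped, 0.3, seed=53)
        res = nrvat.nrvat_test(Y, X,
                               np.random.default_rng(54).integers(0, 3, (600, 20)),
                               default_ped, weights="flat")
        # Sigma theta_n = tr(K Omega); TestResult keeps the full spectrum sum
        assert res.Q >= 0 and 0 <= res.p_value <= 1

    def test_degenerate_all_zero_weights(self):
        with pytest.raises(c.DegenerateTestError):
            c._theta_to_p(1.0, np.zeros(5), 0, 0.0)


class TestEndToEnd:
    def test_reduces_to_unrelated_sample_kernel_test(self):
        """h2=0, singleton families: Omega collapses to the classic projection
        Delta - Delta X (X' Delta X)^-1 X' Delta, and p matches an independent
        direct implementation of the same formulas."""
        n = 80
        ped = singleton_pedigree(n)
        rng = np.random.default_rng(61)
        X = np.column_stack([np.ones(n), rng.uniform(size=n)])
        mu_t = expit(X @ np.array([-0.5, 1.0]))
        Y = (rng.random(n) < mu_t).astype(float)
        G = rng.integers(0, 3, size=(n, 5)).astype(float)
        w = np.ones(5)

        res = nrvat.nrvat_test(Y, X, G, ped, weights=w, h2=0.0)

        # ---- independent route ----
        import statsmodels.api as sm

        fit = sm.GLM(Y, X, family=sm.families.Binomial()).fit(tol=1e-10)
        mu = fit.fittedvalues
        delta = mu * (1 - mu)
        P0 = np.diag(delta) - (delta[:, None] * X) @ np.linalg.solve(
            (X.T * delta) @ X, (X * delta[:, None]).T)
        K = G @ np.diag(w) @ G.T
        Q_ref = (Y - mu) @ K @ (Y - mu)
        ev, V = np.linalg.eigh(P0)
        S = V @ np.diag(np.sqrt(np.clip(ev, 0, None))) @ V.T
        theta_ref = np.linalg.eigvalsh(S @ K @ S)
        theta_ref = theta_ref[theta_ref > 1e-10 * theta_ref.max()]
        p_ref, _ = c.mixture_chisq_sf(Q_ref, theta_ref)

        assert res.Q == pytest.approx(Q_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_determinism_and_diagnostics(self, default_ped):
        rng = np.random.default_rng(71)
        cfg = nrvat.ExperimentConfig(n_replicates=1, seed=7)
        Y, X, G = nrvat.simulate_dataset(cfg, default_ped, rng)
        r1 = nrvat.nrvat_test(Y, X, G, default_ped)
        r2 = nrvat.nrvat_test(Y, X, G, default_ped)
        assert r1.p_value == r2.p_value and r1.Q == r2.Q
        assert 0 <= r1.h2_hat < 1
        assert r1.r_effective <= 20
        assert r1.trace_k_delta > 0

    def test_fixed_h2_and_empirical_b(self, default_ped):
        rng = np.random.default_rng(72)
        cfg = nrvat.ExperimentConfig(n_replicates=1, seed=8)
        Y, X, G = nrvat.simulate_dataset(cfg, default_ped, rng)
        r = nrvat.nrvat_test(Y, X, G, default_ped, h2=0.5, b_mode="empirical")
        assert r.h2_hat == 0.5
        assert 0 < r.p_value <= 1
        with pytest.raises(ValueError):
            nrvat.nrvat_test(Y, X, G, default_ped, h2=1.5)

    def test_monomorphic_region_errors(self, default_ped):
        rng = np.random.default_rng(73)
        cfg = nrvat.ExperimentConfig(n_replicates=1, seed=9)
        Y, X, _ = nrvat.simulate_dataset(cfg, default_ped, rng)
        G0 = np.zeros((600, 4))
        with pytest.raises(c.DegenerateTestError):
            nrvat.nrvat_test(Y, X, G0, default_ped)

    def test_few_families_warning_note(self):
        ped = nrvat.default_pedigree_set(4, 3, 3)
        rng = np.random.default_rng(74)
        cfg = nrvat.ExperimentConfig(n_replicates=1, seed=10, n_trio=4,
                                     n_quad=3, n_octet=3)
        Y, X, G = nrvat.simulate_dataset(cfg, ped, rng)
        r = nrvat.nrvat_test(Y, X, G, ped)
        assert any("families" in w for w in r.warnings)
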