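"""Closed-form identities, sampler recovery and optimization properties of
the seven prediction models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenogp import predictors as P


def centered_orthonormal(rng, n, p):
    """Orthonormal columns orthogonal to the intercept (mean-zero)."""
    A = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:]


# --------------------------------------------------------------------------
# ridge


class TestRidge:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        lam = float(rng.uniform(0.1, 10))
        fit = P.fit_ridge(X, y, lam, standardize=False)
        Xc = X - X.mean(axis=0)
        expected = np.linalg.solve(Xc.T @ Xc + lam * np.eye(10),
                                   Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(fit.coef[:, 0], expected, atol=1e-8)

    def test_identity_design_example(self):
        # X = I2, y = (1, 2), lam = 1 -> b = (0.5, 1.0); prediction example
        b = P._ridge_coef(np.eye(2), np.array([1.0, 2.0]).reshape(-1, 1), 1.0)
        np.testing.assert_allclose(b[:, 0], [0.5, 1.0])

    def test_zero_penalty_is_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        fit = P.fit_ridge(X, y, 0.0, standardize=False)
        Xc = X - X.mean(axis=0)
        ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(fit.coef[:, 0], ols, atol=1e-8)

    def test_infinite_shrinkage(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        fit = P.fit_ridge(X, y, 1e8, standardize=False)
        assert np.abs(fit.coef).max() < 1e-4

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            P.fit_ridge(np.array([[np.nan, 1.0]]), np.array([1.0]), 1.0)

    def test_path_matches_single_fits(self, rng):
        X = rng.normal(size=(15, 30))  # p > n exercises the dual path
        Y = rng.normal(size=(15, 2))
        grid = [{"lam": l} for l in (0.5, 3.0, 20.0)]
        path = P.fit_path("RR", X, Y, grid)
        for h, f in zip(grid, path):
            single = P.fit_ridge(X, Y, h["lam"])
            np.testing.assert_allclose(f.coef, single.coef, atol=1e-8)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_ridge_norm_decreases_with_penalty(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(15, 8))
    y = rng.normal(size=15)
    norms = [np.linalg.norm(P.fit_ridge(X, y, lam).coef)
             for lam in (0.1, 1.0, 10.0, 100.0)]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


# --------------------------------------------------------------------------
# LASSO / EN


class TestLasso:
    @pytest.mark.parametrize("seed", range(5))
    def test_soft_threshold_on_orthonormal_design(self, seed):
        rng = np.random.default_rng(seed)
        X = centered_orthonormal(rng, 25, 10)
        y = X @ (rng.normal(size=10) * 3) + 0.05 * rng.normal(size=25)
        lam = 1.0
        fit = P.fit_mlasso(X, y, lam, standardize=False, tol=1e-10)
        bo = X.T @ (y - y.mean())
        soft = np.sign(bo) * np.maximum(np.abs(bo) - lam / 2, 0.0)
        np.testing.assert_allclose(fit.coef[:, 0], soft, atol=1e-6)

    def test_zero_penalty_is_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        fit = P.fit_mlasso(X, y, 0.0, standardize=False)
        Xc = X - X.mean(axis=0)
        ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(fit.coef[:, 0], ols, atol=1e-8)

    def test_above_lambda_max_gives_exact_zero(self, rng):
        X = rng.normal(size=(40, 12))
        y = rng.normal(size=40)
        Xc = X - X.mean(axis=0)
        lam_max = 2 * np.abs(Xc.T @ (y - y.mean())).max()
        fit = P.fit_mlasso(X, y, lam_max * 1.001, standardize=False)
        assert np.all(fit.coef == 0)

    def test_multiresponse_separates_per_column(self, rng):
        X = rng.normal(size=(30, 8))
        Y = rng.normal(size=(30, 3))
        joint = P.fit_mlasso(X, Y, 2.0)
        for k in range(3):
            single = P.fit_mlasso(X, Y[:, k], 2.0)
            np.testing.assert_allclose(joint.coef[:, k], single.coef[:, 0],
                                       atol=1e-10)


class TestElasticNet:
    def test_reduces_to_ridge(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        en = P.fit_elastic_net(X, y, lam1=3.0, lam2=0.0)
        rr = P.fit_ridge(X, y, 3.0)
        np.testing.assert_allclose(en.coef, rr.coef, atol=1e-8)

    def test_reduces_to_lasso(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        en = P.fit_elastic_net(X, y, lam1=0.0, lam2=2.0)
        la = P.fit_mlasso(X, y, 2.0)
        np.testing.assert_allclose(en.coef, la.coef, atol=1e-8)

    def test_both_zero_is_ols(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        en = P.fit_elastic_net(X, y, 0.0, 0.0, standardize=False)
        Xc = X - X.mean(axis=0)
        ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(en.coef[:, 0], ols, atol=1e-8)

    def test_objective_beats_perturbations(self, rng):
        # direct check of the declared objective at the solution
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        lam1, lam2 = 1.5, 2.5
        fit = P.fit_elastic_net(X, y, lam1, lam2, standardize=False, tol=1e-10)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()

        def obj(b):
            return (np.sum((yc - Xc @ b) ** 2) + lam1 * np.sum(b ** 2)
                    + lam2 * np.sum(np.abs(b)))

        b_hat = fit.coef[:, 0]
        base = obj(b_hat)
        for _ in range(30):
            assert base <= obj(b_hat + rng.normal(size=6) * 0.01) + 1e-9


# --------------------------------------------------------------------------
# GBLUP


class TestGBLUP:
    @pytest.mark.parametrize("seed", range(10))
    def test_equivalent_to_marker_ridge(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(20, 10)).astype(float)
        y = ((X - X.mean(axis=0)) @ rng.normal(size=10) * 0.5
             + rng.normal(size=20))
        mm = P.fit_gblup(X, y)
        lam = mm.sigma_e2 / max(mm.sigma_u2, 1e-12)
        rr = P.fit_ridge(X, y, lam, standardize=False)
        X_new = rng.integers(0, 3, size=(6, 10)).astype(float)
        np.testing.assert_allclose(P.predict(mm, X_new), P.predict(rr, X_new),
                                   atol=1e-6)

    def test_constant_response(self):
        X = np.random.default_rng(0).integers(0, 3, size=(15, 8)).astype(float)
        mm = P.fit_gblup(X, np.full(15, 3.3))
        assert mm.sigma_u2 == 0
        np.testing.assert_allclose(P.predict(mm, X), 3.3)

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(3)
        n, p = 300, 150
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        Z = X - X.mean(axis=0)
        b = rng.normal(size=p) * np.sqrt(2.0 / p)
        g = Z @ b
        y = g + rng.normal(size=n) * 1.0
        mm = P.fit_gblup(X, y)
        h2_hat = (mm.u.var() / y.var())
        h2_true = g.var() / y.var()
        assert abs(h2_hat - h2_true) < 0.25


# --------------------------------------------------------------------------
# Bayesian samplers


class TestBayesianLasso:
    def test_high_signal_recovery_and_determinism(self):
        rng = np.random.default_rng(42)
        n, p = 200, 50
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        b_true = np.zeros(p)
        b_true[:10] = rng.normal(size=10) * 2
        g = (X - X.mean(axis=0)) @ b_true
        y = g + rng.normal(size=n) * np.sqrt(g.var() / 9)  # h2 ~ 0.9
        fit = P.fit_bayesian_lasso(X, y, chain_length=2000, burn_in=500, seed=1)
        b_hat = fit.coef[:, 0] / fit.standardizer.scale
        assert np.corrcoef(b_hat, b_true)[0, 1] >= 0.9
        fit2 = P.fit_bayesian_lasso(X, y, chain_length=2000, burn_in=500, seed=1)
        np.testing.assert_array_equal(fit.coef, fit2.coef)

    def test_zero_column_gets_zero_posterior_mean(self, rng):
        X = rng.normal(size=(60, 5))
        X[:, 2] = 0.0
        y = X[:, 0] * 2 + rng.normal(size=60) * 0.1
        fit = P.fit_bayesian_lasso(X, y, chain_length=1500, burn_in=300,
                                   seed=2, standardize=False)
        assert abs(fit.coef[2, 0]) < 0.05

    def test_chain_shorter_than_burnin_rejected(self, rng):
        with pytest.raises(ValueError):
            P.fit_bayesian_lasso(rng.normal(size=(10, 2)), rng.normal(size=10),
                                 chain_length=100, burn_in=100)


class TestMBayesB:
    def test_trait_specific_inclusion_ranking(self):
        rng = np.random.default_rng(7)
        n, p, t = 150, 100, 2
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        B = np.zeros((p, t))
        B[:8, 0] = rng.normal(size=8) * 1.5  # causal for trait 1 only
        G = (X - X.mean(axis=0)) @ B
        Y = G + rng.normal(size=(n, t)) * np.sqrt(np.maximum(G.var(axis=0), 1) / 4)
        cfg = P.MBayesBConfig(chain_length=1200, burn_in=300, seed=3)
        fit = P.fit_mbayesb(X, Y, cfg)
        incl = fit.inclusion
        assert incl[:8, 0].mean() >= 2 * max(incl[8:, 0].mean(), 1e-3)
        assert incl[:8, 0].mean() > incl[:8, 1].mean()

    def test_single_trait_reduction_runs(self, rng):
        X = rng.integers(0, 3, size=(50, 30)).astype(float)
        y = (X - X.mean(axis=0))[:, 0] * 2 + rng.normal(size=50) * 0.5
        fit = P.fit_mbayesb(X, y, P.MBayesBConfig(chain_length=600, burn_in=150,
                                                  seed=1))
        assert fit.coef.shape == (30, 1)
        assert fit.inclusion[0, 0] > 0.5

    def test_full_inclusion_approaches_multivariate_ridge(self, rng):
        # pi = 1: every locus always included; the fit behaves like a
        # shrinkage (ridge-type) regression
        X = rng.normal(size=(80, 10))
        B_true = rng.normal(size=(10, 2))
        Y = X @ B_true + rng.normal(size=(80, 2)) * 0.3
        cfg = P.MBayesBConfig(inclusion_prob=1.0, chain_length=1500,
                              burn_in=300, seed=5)
        fit = P.fit_mbayesb(X, Y, cfg, standardize=False)
        assert np.all(fit.inclusion == 1.0)
        rr = P.fit_ridge(X, Y, 1.0, standardize=False)
        for k in range(2):
            assert np.corrcoef(fit.coef[:, k], rr.coef[:, k])[0, 1] > 0.95

    def test_bad_df_rejected(self, rng):
        cfg = P.MBayesBConfig(df=1.0)
        with pytest.raises(ValueError, match="df must exceed"):
            P.fit_mbayesb(rng.normal(size=(20, 5)), rng.normal(size=(20, 3)), cfg)

    def test_reproducible_under_seed(self, rng):
        X = rng.normal(size=(30, 15))
        Y = rng.normal(size=(30, 2))
        cfg = P.MBayesBConfig(chain_length=300, burn_in=50, seed=11)
        f1 = P.fit_mbayesb(X, Y, cfg)
        f2 = P.fit_mbayesb(X, Y, cfg)
        np.testing.assert_array_equal(f1.coef, f2.coef)


# --------------------------------------------------------------------------
# L21-joint


class TestL21Joint:
    @pytest.mark.parametrize("seed", range(5))
    def test_objective_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 20))
        Y = rng.normal(size=(30, 3))
        fit = P.fit_l21_joint(X, Y, lam1=0.1, lam2=1.0)
        obj = fit.diagnostics["objective"]
        assert np.all(np.diff(obj) <= 1e-8)

    def test_large_row_penalty_decouples(self, rng):
        X = rng.normal(size=(40, 10))
        Y = rng.normal(size=(40, 3))
        fit = P.fit_l21_joint(X, Y, lam1=0.05, lam2=1e7, standardize=False)
        assert np.all(fit.coef == 0)
        from sklearn.covariance import graphical_lasso
        Yc = Y - Y.mean(axis=0)
        _, omega = graphical_lasso(Yc.T @ Yc / 40, alpha=0.05)
        np.testing.assert_allclose(fit.omega, omega, atol=1e-8)

    def test_unpenalized_with_identity_omega_is_ols(self, rng):
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 3))
        fit = P.fit_l21_joint(X, Y, 0.0, 0.0, omega_fixed=np.eye(3),
                              standardize=False)
        Xc = X - X.mean(axis=0)
        ols = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols, atol=1e-6)

    def test_omega_symmetric_positive_definite(self, rng):
        X = rng.normal(size=(35, 12))
        Y = rng.normal(size=(35, 4))
        fit = P.fit_l21_joint(X, Y, lam1=0.2, lam2=0.5)
        np.testing.assert_allclose(fit.omega, fit.omega.T)
        assert np.linalg.eigvalsh(fit.omega).min() > 0

    def test_row_sparsity_shared_across_traits(self, rng):
        X = rng.normal(size=(60, 15))
        B = np.zeros((15, 2))
        B[:3] = np.array([[2.0, -2.0], [2.5, 1.5], [-2.0, 2.0]])
        Y = X @ B + rng.normal(size=(60, 2)) * 0.3
        fit = P.fit_l21_joint(X, Y, lam1=0.05, lam2=1.0, standardize=False)
        row_norms = np.linalg.norm(fit.coef, axis=1)
        assert (row_norms[3:] == 0).mean() > 0.5
        assert row_norms[:3].min() > 0

    def test_single_response_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            P.fit_l21_joint(rng.normal(size=(20, 5)), rng.normal(size=20))


# --------------------------------------------------------------------------
# predict contract


class TestPredict:
    def test_in_sample_fitted_values(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        fit = P.fit_ridge(X, y, 1.0)
        pred = P.predict(fit, X)
        Xs = fit.standardizer.transform(X)
        np.testing.assert_allclose(pred, fit.intercept + Xs @ fit.coef[:, 0])

    def test_zero_coefficients_predict_intercept(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        fit = P.fit_mlasso(X, y, 1e9)
        np.testing.assert_allclose(P.predict(fit, X), y.mean())

    def test_identity_ridge_prediction_example(self):
        fit = P.FitResult("RR", np.array([[0.5], [1.0]]), np.array([0.0]),
                          P.Standardizer(np.zeros(2), np.ones(2), False),
                          squeeze=True)
        np.testing.assert_allclose(P.predict(fit, np.eye(2)), [0.5, 1.0])

    def test_column_mismatch_rejected(self, rng):
        import pandas as pd
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        fit = P.fit_ridge(X, rng.normal(size=20), 1.0)
        bad = X.rename(columns={"c": "z"})
        with pytest.raises(ValueError, match="do not match"):
            P.predict(fit, bad)
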