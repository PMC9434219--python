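"""The seven prediction models behind one common fit/predict contract.

Single-trait: ridge regression (RR), LASSO, elastic net (EN), GBLUP,
Bayesian LASSO (BL).  Multi-trait: mBayesB (mixture-prior variable
selection with locus-specific effect covariances) and L21-joint
(row-sparse multivariate regression with joint sparse precision-matrix
estimation).  RR/mLASSO/EN accept multi-column responses directly (their
objectives separate across columns).

Penalty convention: all penalized objectives are exposed on the unscaled
residual-sum-of-squares form

    ||y - Xb||^2 + lambda * penalty(b)

Internally LASSO and elastic net are solved by scikit-learn's coordinate
descent, whose 1/(2n)-scaled convention is converted as alpha = lambda/(2n)
(and the elastic-net pair (lambda1 L2, lambda2 L1) maps to
alpha = (lambda2 + 2*lambda1)/(2n), l1_ratio = lambda2/(lambda2 + 2*lambda1)).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.linear_model import ElasticNet, Lasso, enet_path, lasso_path

METHOD_IDS = ("RR", "mLASSO", "EN", "GBLUP", "BL", "mBayesB", "L21-joint")
#: methods that carry tunable hyperparameters (inner-CV selection)
GRID_METHODS = ("RR", "mLASSO", "EN", "L21-joint")
#: multi-trait-native methods
MULTITRAIT_METHODS = ("mBayesB", "L21-joint", "RR", "mLASSO", "EN")


# --------------------------------------------------------------------------
# design handling


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    return X, None


def _as_response(Y) -> tuple[np.ndarray, list[str] | None, bool]:
    names = None
    if isinstance(Y, pd.DataFrame):
        names = [str(c) for c in Y.columns]
        arr = Y.to_numpy(float)
    elif isinstance(Y, pd.Series):
        names = [str(Y.name) if Y.name is not None else "y"]
        arr = Y.to_numpy(float).reshape(-1, 1)
        return arr, names, True
    else:
        arr = np.asarray(Y, float)
    if arr.ndim == 1:
        return arr.reshape(-1, 1), names, True
    return arr, names, False


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in model input")


@dataclasses.dataclass
class Standardizer:
    """Per-column centering/scaling learned on the training design."""

    mean: np.ndarray
    scale: np.ndarray
    enabled: bool = True

    @classmethod
    def fit(cls, X: np.ndarray, standardize: bool) -> "Standardizer":
        mean = X.mean(axis=0)
        if standardize:
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
        else:
            scale = np.ones(X.shape[1])
        return cls(mean, scale, standardize)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclasses.dataclass
class FitResult:
    """Coefficients (on the transformed predictor scale), intercepts,
    chosen hyperparameters and diagnostics for a linear-predictor fit."""

    method: str
    coef: np.ndarray                       # p x t
    intercept: np.ndarray                  # t
    standardizer: Standardizer
    hyperparams: dict = dataclasses.field(default_factory=dict)
    predictor_names: list[str] | None = None
    response_names: list[str] | None = None
    omega: np.ndarray | None = None        # t x t precision (L21-joint)
    inclusion: np.ndarray | None = None    # p x t inclusion freq (mBayesB)
    diagnostics: dict = dataclasses.field(default_factory=dict)
    squeeze: bool = False                  # 1-D response on input

    def to_json_dict(self) -> dict:
        out = {"method": self.method, "coef": self.coef.tolist(),
               "intercept": self.intercept.tolist(),
               "hyperparams": {k: (float(v) if np.isscalar(v) else v)
                               for k, v in self.hyperparams.items()},
               "diagnostics": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                               for k, v in self.diagnostics.items()}}
        if self.omega is not None:
            out["omega"] = self.omega.tolist()
        return out


@dataclasses.dataclass
class MixedModelFit:
    """GBLUP fit: variance components, relationship matrix and BLUPs."""

    sigma_u2: float
    sigma_e2: float
    K: np.ndarray
    u: np.ndarray                 # BLUPs for training samples
    mu: float
    marker_effects: np.ndarray    # equivalent ridge effects (centered scale)
    col_means: np.ndarray
    predictor_names: list[str] | None = None
    response_names: list[str] | None = None
    method: str = "GBLUP"
    squeeze: bool = True

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")


@dataclasses.dataclass
class MultiFit:
    """Wrapper around independent per-response-column fits."""

    method: str
    fits: list
    response_names: list[str] | None = None
    predictor_names: list[str] | None = None
    squeeze: bool = False


@dataclasses.dataclass
class MBayesBConfig:
    """mBayesB prior and chain settings.

    ``inclusion_prob`` is the prior probability that a locus affects a given
    trait; ``df``/``scale_mult`` parameterize the inverse-Wishart prior on
    the locus-specific effect covariance (df defaults to t + 4, scale to
    0.1 * I).
    """

    inclusion_prob: float = 0.05
    df: float | None = None
    scale_mult: float = 0.1
    chain_length: int = 20000
    burn_in: int = 5000
    seed: int = 0

    def validate(self, t: int) -> None:
        if not 0.0 < self.inclusion_prob <= 1.0:
            raise ValueError("inclusion probability must lie in (0, 1]")
        df = self.df if self.df is not None else t + 4
        if df <= t - 1:
            raise ValueError(f"inverse-Wishart df must exceed t - 1 = {t - 1}")
        if self.chain_length <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")


# --------------------------------------------------------------------------
# ridge


def _ridge_coef(Xs: np.ndarray, Yc: np.ndarray, lam: float) -> np.ndarray:
    """argmin ||y - Xb||^2 + lam ||b||^2, columnwise; primal or dual."""
    n, p = Xs.shape
    if lam == 0:
        return np.linalg.lstsq(Xs, Yc, rcond=None)[0]
    if p <= n:
        A = Xs.T @ Xs + lam * np.eye(p)
        return np.linalg.solve(A, Xs.T @ Yc)
    G = Xs @ Xs.T + lam * np.eye(n)
    return Xs.T @ np.linalg.solve(G, Yc)


def fit_ridge(X, Y, lam: float = 1.0, *, standardize: bool = True) -> FitResult:
    """Ridge regression on the unscaled convention (closed form)."""
    Xa, xnames = _as_matrix(X)
    Ya, ynames, squeeze = _as_response(Y)
    _check_finite(Xa, Ya)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    std = Standardizer.fit(Xa, standardize)
    Xs = std.transform(Xa)
    ybar = Ya.mean(axis=0)
    B = _ridge_coef(Xs, Ya - ybar, float(lam))
    return FitResult("RR", B, ybar, std, {"lam": float(lam)},
                     xnames, ynames, squeeze=squeeze)


def _ridge_path(Xs, Yc, lams: Sequence[float]) -> list[np.ndarray]:
    """Ridge coefficients for many lambdas from one eigendecomposition."""
    n, p = Xs.shape
    out = []
    if p <= n:
        evals, U = np.linalg.eigh(Xs.T @ Xs)
        XtY = Xs.T @ Yc
        UtXtY = U.T @ XtY
        for lam in lams:
            out.append(U @ (UtXtY / (evals + lam)[:, None]))
    else:
        evals, U = np.linalg.eigh(Xs @ Xs.T)
        UtY = U.T @ Yc
        XtU = Xs.T @ U
        for lam in lams:
            out.append(XtU @ (UtY / (evals + lam)[:, None]))
    return out


# --------------------------------------------------------------------------
# LASSO / elastic net (scikit-learn backend, converted convention)


def fit_mlasso(X, Y, lam: float = 1.0, *, standardize: bool = True,
               tol: float = 1e-6, max_iter: int = 20000) -> FitResult:
    """(Multi-response) LASSO: ||Y - XB||^2 + lam ||B||_1 (elementwise L1).

    The objective separates across response columns, so each column is an
    independent LASSO problem.
    """
    Xa, xnames = _as_matrix(X)
    Ya, ynames, squeeze = _as_response(Y)
    _check_finite(Xa, Ya)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    std = Standardizer.fit(Xa, standardize)
    Xs = std.transform(Xa)
    n = Xs.shape[0]
    ybar = Ya.mean(axis=0)
    if lam == 0:
        B = np.linalg.lstsq(Xs, Ya - ybar, rcond=None)[0]
    else:
        model = Lasso(alpha=lam / (2 * n), fit_intercept=False, tol=tol,
                      max_iter=max_iter)
        B = np.column_stack([model.fit(Xs, Ya[:, k] - ybar[k]).coef_
                             for k in range(Ya.shape[1])])
    return FitResult("mLASSO", B, ybar, std, {"lam": float(lam)},
                     xnames, ynames, squeeze=squeeze)


def fit_elastic_net(X, Y, lam1: float = 0.0, lam2: float = 1.0, *,
                    standardize: bool = True, tol: float = 1e-6,
                    max_iter: int = 20000) -> FitResult:
    """Elastic net: ||y - Xb||^2 + lam1 ||b||^2 + lam2 ||b||_1."""
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be nonnegative")
    if lam2 == 0:
        fit = fit_ridge(X, Y, lam=lam1, standardize=standardize)
    elif lam1 == 0:
        fit = fit_mlasso(X, Y, lam=lam2, standardize=standardize,
                         tol=tol, max_iter=max_iter)
    else:
        Xa, xnames = _as_matrix(X)
        Ya, ynames, squeeze = _as_response(Y)
        _check_finite(Xa, Ya)
        std = Standardizer.fit(Xa, standardize)
        Xs = std.transform(Xa)
        n = Xs.shape[0]
        ybar = Ya.mean(axis=0)
        a = lam2 / (2 * n)
        b = lam1 / (2 * n)
        alpha = a + 2 * b
        l1_ratio = a / alpha
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
                           tol=tol, max_iter=max_iter)
        B = np.column_stack([model.fit(Xs, Ya[:, k] - ybar[k]).coef_
                             for k in range(Ya.shape[1])])
        return FitResult("EN", B, ybar, std,
                         {"lam1": float(lam1), "lam2": float(lam2)},
                         xnames, ynames, squeeze=squeeze)
    fit.method = "EN"
    fit.hyperparams = {"lam1": float(lam1), "lam2": float(lam2)}
    return fit


# --------------------------------------------------------------------------
# GBLUP


def fit_gblup(X, y, *, scale_k: bool = False, ridge_eps: float = 1e-8,
              bounds: tuple[float, float] = (-8.0, 8.0)) -> MixedModelFit:
    """GBLUP: y = 1*mu + u + e with u ~ N(0, sigma_u2 * K), K = Z Z'.

    Z is the column-centered marker matrix (optionally K = Z Z' / p with
    ``scale_k``).  Variance components are estimated by profile REML on the
    eigendecomposition of K; predictions for unseen samples go through the
    cross-relationship block, equivalently the stored ridge marker effects.
    """
    from scipy.optimize import minimize_scalar

    Xa, xnames = _as_matrix(X)
    ya, ynames, _ = _as_response(y)
    if ya.shape[1] != 1:
        raise ValueError("GBLUP is single-response; fit per column")
    yv = ya[:, 0]
    _check_finite(Xa, yv)
    n = len(yv)
    col_means = Xa.mean(axis=0)
    Z = Xa - col_means
    K = Z @ Z.T
    if scale_k:
        K /= Xa.shape[1]
        Z = Z / np.sqrt(Xa.shape[1])
    K[np.diag_indices_from(K)] += ridge_eps
    mu = yv.mean()
    yc = yv - mu
    if yc.std() == 0:
        return MixedModelFit(0.0, 0.0, K, np.zeros(n), mu,
                             np.zeros(Xa.shape[1]), col_means, xnames, ynames)
    # REML on the intercept contrast space: eigenvalues of P(K+I)P separate
    # the 1-direction (eigenvalue 0) from the n-1 contrasts (>= 1)
    P = np.eye(n) - np.full((n, n), 1.0 / n)
    evals, U = np.linalg.eigh(P @ (K + np.eye(n)) @ P)
    keep = np.argsort(evals)[1:]             # drop the projected-out direction
    xi = np.clip(evals[keep] - 1.0, 0.0, None)
    eta = U[:, keep].T @ yc

    def neg_reml(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        d = xi + delta
        sigma_u2 = float(np.sum(eta ** 2 / d) / (n - 1))
        ll = -0.5 * ((n - 1) * np.log(max(sigma_u2, 1e-300)) + np.sum(np.log(d)))
        return -ll

    res = minimize_scalar(neg_reml, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    delta = 10.0 ** float(res.x)
    d = xi + delta
    sigma_u2 = float(np.sum(eta ** 2 / d) / (n - 1))
    sigma_e2 = sigma_u2 * delta
    alpha = np.linalg.solve(K + delta * np.eye(n), yc)
    u = K @ alpha
    b = Z.T @ alpha                  # equivalent marker ridge effects
    return MixedModelFit(sigma_u2, sigma_e2, K, u, mu, b, col_means,
                         xnames, ynames)


# --------------------------------------------------------------------------
# Bayesian LASSO


def fit_bayesian_lasso(X, y, *, chain_length: int = 20000, burn_in: int = 5000,
                       seed: int = 0, standardize: bool = True,
                       lambda_shape: float = 1.0, lambda_rate: float = 0.1
                       ) -> FitResult:
    """Bayesian LASSO via the normal-exponential scale-mixture Gibbs sampler.

    Laplace priors on effects; the squared regularization parameter carries
    a Gamma(lambda_shape, lambda_rate) hyperprior.  Returns posterior-mean
    coefficients; reproducible under a fixed seed.
    """
    from ._samplers import bl_gibbs

    Xa, xnames = _as_matrix(X)
    ya, ynames, _ = _as_response(y)
    if ya.shape[1] != 1:
        raise ValueError("Bayesian LASSO is single-response; fit per column")
    if chain_length <= burn_in:
        raise ValueError("chain length must exceed burn-in")
    yv = ya[:, 0]
    _check_finite(Xa, yv)
    std = Standardizer.fit(Xa, standardize)
    Xs = std.transform(Xa)
    b, mu, s2, lam, ok = bl_gibbs(
        np.ascontiguousarray(Xs), np.ascontiguousarray(yv),
        int(chain_length), int(burn_in), int(seed) % (2 ** 31),
        float(lambda_shape), float(lambda_rate))
    if not ok:
        raise RuntimeError("Bayesian LASSO chain diverged (non-finite state)")
    return FitResult("BL", b.reshape(-1, 1), np.array([mu]), std,
                     {"chain_length": chain_length, "burn_in": burn_in},
                     xnames, ynames,
                     diagnostics={"sigma2": s2, "lambda": lam}, squeeze=True)


# --------------------------------------------------------------------------
# multi-trait BayesB


def fit_mbayesb(X, Y, config: MBayesBConfig | None = None, *,
                standardize: bool = True) -> FitResult:
    """Multi-trait BayesB: per-locus inclusion indicators over any subset of
    traits, effect vectors with locus-specific inverse-Wishart covariances,
    sampled residual covariance.  Returns posterior-mean effects and
    per-locus per-trait inclusion frequencies."""
    from ._samplers import mbayesb_gibbs

    config = config or MBayesBConfig()
    Xa, xnames = _as_matrix(X)
    Ya, ynames, squeeze = _as_response(Y)
    _check_finite(Xa, Ya)
    t = Ya.shape[1]
    config.validate(t)
    std = Standardizer.fit(Xa, standardize)
    Xs = std.transform(Xa)
    df = config.df if config.df is not None else t + 4
    S_prior = config.scale_mult * np.eye(t)
    nu_r = t + 2.0
    S_r = np.diag(np.maximum(Ya.var(axis=0), 1e-8)) * 0.5
    B, incl, mu, ok = mbayesb_gibbs(
        np.ascontiguousarray(Xs), np.ascontiguousarray(Ya),
        int(config.chain_length), int(config.burn_in),
        float(config.inclusion_prob), float(df),
        np.ascontiguousarray(S_prior), nu_r, np.ascontiguousarray(S_r),
        int(config.seed) % (2 ** 31))
    if not ok:
        raise RuntimeError("mBayesB chain diverged (non-finite state)")
    return FitResult("mBayesB", B, mu, std,
                     {"inclusion_prob": config.inclusion_prob, "df": df,
                      "chain_length": config.chain_length,
                      "burn_in": config.burn_in},
                     xnames, ynames, inclusion=incl, squeeze=squeeze)


# --------------------------------------------------------------------------
# L21-joint


def _l21_objective(Xs, Yc, B, omega, s, lam1, lam2) -> float:
    R = Yc - Xs @ B
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return np.inf
    off = np.abs(omega).sum() - np.abs(np.diag(omega)).sum()
    rows = np.sqrt((B ** 2).sum(axis=1)).sum()
    return float(np.trace(R @ omega @ R.T) / s - logdet
                 + lam1 * off + lam2 * rows)


def _row_soft_threshold(B: np.ndarray, thresh: float) -> np.ndarray:
    norms = np.sqrt((B ** 2).sum(axis=1))
    scale = np.zeros_like(norms)
    nz = norms > thresh
    scale[nz] = 1.0 - thresh / norms[nz]
    return B * scale[:, None]


def _l21_b_step(Xs, Yc, B, omega, s, lam2, x_spec_norm, XtY,
                max_steps: int = 200, tol: float = 1e-9) -> np.ndarray:
    """Proximal-gradient (ISTA with backtracking) for the row-sparse B update.

    Gradients are formed as X'((XB - Y) @ omega), O(n p t) per step, so
    wide (p >> n) marker designs stay cheap; the Lipschitz constant uses the
    precomputed spectral norm of X.
    """
    if lam2 == 0:
        # unpenalized weighted LS: stationarity X'(XB - Y) @ omega = 0 with
        # omega PD reduces to ordinary least squares
        return np.linalg.lstsq(Xs, Yc, rcond=None)[0]

    def smooth(R):
        return float(np.einsum("ij,jk,ik->", R, omega, R)) / s

    L = 2.0 / s * x_spec_norm ** 2 * np.linalg.eigvalsh(omega).max()
    step = 1.0 / max(L, 1e-12)
    XB = Xs @ B
    f = smooth(Yc - XB)
    for _ in range(max_steps):
        grad = 2.0 / s * ((Xs.T @ (XB @ omega)) - XtY @ omega)
        while True:
            B_new = _row_soft_threshold(B - step * grad, step * lam2)
            D = B_new - B
            XB_new = Xs @ B_new
            f_new = smooth(Yc - XB_new)
            # sufficient-decrease (majorization) check
            if f_new <= f + np.sum(grad * D) + np.sum(D ** 2) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-16:
                B_new, f_new, XB_new = B, f, XB
                break
        change = np.abs(B_new - B).max()
        B, f, XB = B_new, f_new, XB_new
        if change < tol:
            break
    return B


def fit_l21_joint(X, Y, lam1: float = 0.1, lam2: float = 1.0, *,
                  tol: float = 1e-6, max_iter: int = 500, inner_steps: int = 200,
                  standardize: bool = True, omega_fixed: np.ndarray | None = None,
                  ridge_eps: float = 1e-6) -> FitResult:
    """L2,1-regularized multivariate regression with joint sparse precision
    estimation.

    Alternates (i) a proximal-gradient update of B under the row-group
    (L2,1) penalty with the residuals weighted by the current precision
    matrix Omega, and (ii) an L1-penalized precision (graphical-lasso)
    update of Omega on the residual scatter (1/s)(Y-XB)'(Y-XB), where s is
    the training sample count.  Stops when the relative objective decrease
    falls below ``tol`` or after ``max_iter`` alternations.  A non-PD
    residual scatter is ridged on the diagonal by ``ridge_eps``.
    """
    Xa, xnames = _as_matrix(X)
    Ya, ynames, squeeze = _as_response(Y)
    _check_finite(Xa, Ya)
    if Ya.shape[1] < 2:
        raise ValueError("L21-joint requires at least 2 response columns")
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be nonnegative")
    std = Standardizer.fit(Xa, standardize)
    Xs = std.transform(Xa)
    s = Xs.shape[0]
    t = Ya.shape[1]
    ybar = Ya.mean(axis=0)
    Yc = Ya - ybar

    def omega_step(B):
        if omega_fixed is not None:
            return np.asarray(omega_fixed, float)
        R = Yc - Xs @ B
        S_r = R.T @ R / s
        S_r = 0.5 * (S_r + S_r.T)
        if np.linalg.eigvalsh(S_r).min() < ridge_eps:
            S_r = S_r + ridge_eps * np.eye(t)
        if lam1 == 0:
            return np.linalg.inv(S_r)
        # the glasso solver can reject PD-but-ill-conditioned scatters;
        # escalate the diagonal ridge before falling back to the ridged
        # inverse (an unpenalized but well-defined precision estimate)
        ridge = ridge_eps
        for _ in range(6):
            try:
                _, omega = graphical_lasso(S_r, alpha=lam1)
                return omega
            except FloatingPointError:
                ridge *= 100.0
                S_r = S_r + ridge * np.eye(t)
        return np.linalg.inv(S_r)

    B = np.zeros((Xs.shape[1], t))
    # start from omega = I and update B first: estimating omega from the
    # zero-coefficient residuals would absorb unfit signal as "correlated
    # noise" before the regression has a chance to explain it
    omega = np.eye(t) if omega_fixed is None else np.asarray(omega_fixed, float)
    objectives = [_l21_objective(Xs, Yc, B, omega, s, lam1, lam2)]
    x_spec_norm = float(np.linalg.svd(Xs, compute_uv=False)[0]) if Xs.size else 0.0
    XtY = Xs.T @ Yc
    for it in range(max_iter):
        B = _l21_b_step(Xs, Yc, B, omega, s, lam2, x_spec_norm, XtY,
                        max_steps=inner_steps)
        omega = omega_step(B)
        obj = _l21_objective(Xs, Yc, B, omega, s, lam1, lam2)
        objectives.append(obj)
        prev = objectives[-2]
        if abs(prev - obj) <= tol * (1.0 + abs(prev)):
            break
    omega = 0.5 * (omega + omega.T)
    return FitResult("L21-joint", B, ybar, std,
                     {"lam1": float(lam1), "lam2": float(lam2)},
                     xnames, ynames, omega=omega,
                     diagnostics={"objective": np.array(objectives),
                                  "iterations": len(objectives) - 1},
                     squeeze=squeeze)


# --------------------------------------------------------------------------
# prediction


def _check_columns(fit_names, X_new_names) -> None:
    if fit_names is None or X_new_names is None:
        return
    if list(fit_names) != list(X_new_names):
        missing = [c for c in fit_names if c not in set(X_new_names)]
        extra = [c for c in X_new_names if c not in set(fit_names)]
        raise ValueError("predictor columns do not match the training design; "
                         f"missing={missing[:5]} extra={extra[:5]}")


def predict(fit, X_new) -> np.ndarray:
    """Deterministic linear prediction: intercept + transform(X_new) @ B,
    or the relationship-based GBLUP prediction."""
    Xa, xnames = _as_matrix(X_new)
    if isinstance(fit, MultiFit):
        _check_columns(fit.predictor_names, xnames)
        cols = [predict(f, Xa).reshape(-1) for f in fit.fits]
        out = np.column_stack(cols)
        return out
    if isinstance(fit, MixedModelFit):
        _check_columns(fit.predictor_names, xnames)
        Z_new = Xa - fit.col_means
        return fit.mu + Z_new @ fit.marker_effects
    _check_columns(fit.predictor_names, xnames)
    if Xa.shape[1] != fit.coef.shape[0]:
        raise ValueError(f"X_new has {Xa.shape[1]} columns, fit expects "
                         f"{fit.coef.shape[0]}")
    pred = fit.intercept + fit.standardizer.transform(Xa) @ fit.coef
    return pred[:, 0] if fit.squeeze else pred


# --------------------------------------------------------------------------
# registry used by the evaluation machinery


def default_grid(method: str, X, Y, n_lam: int = 20, n_mix: int = 5,
                 l21_n: int = 3) -> list[dict]:
    """Hyperparameter candidates per method (empty dict = no tuning).

    Penalized models use a logarithmic grid of ``n_lam`` points spanning
    [1e-4 * lam_max, lam_max] with lam_max = 2 max |X_s'(y - ybar)| on the
    standardized design; the elastic net crosses that grid with ``n_mix``
    L1-mixing levels.
    """
    if method in ("GBLUP", "BL", "mBayesB"):
        return [{}]
    Xa, _ = _as_matrix(X)
    Ya, _, _ = _as_response(Y)
    std = Standardizer.fit(Xa, True)
    Xs = std.transform(Xa)
    Yc = Ya - Ya.mean(axis=0)
    lam_max = 2.0 * np.abs(Xs.T @ Yc).max()
    lam_max = max(lam_max, 1e-6)
    lams = np.geomspace(1e-4 * lam_max, lam_max, n_lam)
    if method == "RR":
        return [{"lam": float(l)} for l in lams]
    if method == "mLASSO":
        return [{"lam": float(l)} for l in lams]
    if method == "EN":
        mixes = np.linspace(0.1, 0.9, n_mix)
        return [{"lam1": float((1 - m) * l), "lam2": float(m * l)}
                for m in mixes for l in lams]
    if method == "L21-joint":
        s = Xs.shape[0]
        lam2_max = max(float(np.sqrt(((Xs.T @ Yc) ** 2).sum(axis=1)).max()
                             * 2.0 / s), 1e-6)
        lam2s = np.geomspace(0.05 * lam2_max, lam2_max, l21_n)
        var_scale = float(np.mean(Yc.var(axis=0))) or 1.0
        lam1s = np.array([0.02, 0.1, 0.4]) * var_scale
        lam1s = lam1s[:l21_n]
        return [{"lam1": float(a), "lam2": float(b)} for a in lam1s for b in lam2s]
    raise ValueError(f"unknown method {method!r}")


def fit_method(method: str, X, Y, hyper: dict | None = None,
               options: dict | None = None):
    """Fit any roster method at given hyperparameters (common contract)."""
    hyper = hyper or {}
    options = dict(options or {})
    standardize = options.pop("standardize", True)
    Ya, ynames, _ = _as_response(Y)
    t = Ya.shape[1]
    cd_kw = {k: options[k] for k in ("tol", "max_iter") if k in options}
    if method == "RR":
        return fit_ridge(X, Y, standardize=standardize, **hyper)
    if method == "mLASSO":
        return fit_mlasso(X, Y, standardize=standardize, **hyper, **cd_kw)
    if method == "EN":
        return fit_elastic_net(X, Y, standardize=standardize, **hyper, **cd_kw)
    if method == "L21-joint":
        kw = {k: options.get("l21_" + k, d) for k, d in
              (("tol", 1e-6), ("max_iter", 500), ("inner_steps", 200))}
        if t < 2:
            raise ValueError("L21-joint requires at least 2 response columns")
        return fit_l21_joint(X, Y, standardize=standardize, **hyper, **kw)
    if method == "GBLUP":
        Xa, xnames = _as_matrix(X)
        if t == 1:
            return fit_gblup(Xa, Ya[:, 0])
        fits = [fit_gblup(Xa, Ya[:, k]) for k in range(t)]
        return MultiFit("GBLUP", fits, ynames, xnames)
    if method == "BL":
        Xa, xnames = _as_matrix(X)
        chain = {k: options[k] for k in ("chain_length", "burn_in", "seed")
                 if k in options}
        if t == 1:
            return fit_bayesian_lasso(Xa, Ya[:, 0], standardize=standardize, **chain)
        fits = [fit_bayesian_lasso(Xa, Ya[:, k], standardize=standardize,
                                   **{**chain, "seed": chain.get("seed", 0) + k})
                for k in range(t)]
        return MultiFit("BL", fits, ynames, xnames)
    if method == "mBayesB":
        cfg = options.get("mbayesb_config")
        if cfg is None:
            cfg = MBayesBConfig(
                chain_length=options.get("mbayesb_chain_length",
                                         options.get("chain_length", 20000)),
                burn_in=options.get("mbayesb_burn_in",
                                    options.get("burn_in", 5000)),
                seed=options.get("seed", 0))
        return fit_mbayesb(X, Y, cfg, standardize=standardize)
    raise ValueError(f"unknown method {method!r}")


def fit_path(method: str, X, Y, grid: list[dict],
             options: dict | None = None) -> list:
    """Fits over a hyperparameter grid, sharing factorizations when possible."""
    options = dict(options or {})
    if method not in ("RR", "mLASSO", "EN") or len(grid) <= 1:
        return [fit_method(method, X, Y, h, options) for h in grid]

    standardize = options.get("standardize", True)
    Xa, xnames = _as_matrix(X)
    Ya, ynames, squeeze = _as_response(Y)
    std = Standardizer.fit(Xa, standardize)
    Xs = std.transform(Xa)
    n = Xs.shape[0]
    ybar = Ya.mean(axis=0)
    Yc = Ya - ybar

    def result(m, B, hyper):
        return FitResult(m, B, ybar, std, hyper, xnames, ynames, squeeze=squeeze)

    if method == "RR":
        lams = [h["lam"] for h in grid]
        coefs = _ridge_path(Xs, Yc, lams)
        return [result("RR", B, {"lam": lam}) for B, lam in zip(coefs, lams)]

    path_tol = options.get("tol", 1e-6)
    if method == "mLASSO":
        lams = np.array([h["lam"] for h in grid])
        order = np.argsort(lams)[::-1]          # warm starts need decreasing alpha
        alphas = lams[order] / (2 * n)
        coef_stack = np.empty((len(grid), Xs.shape[1], Yc.shape[1]))
        for k in range(Yc.shape[1]):
            _, coefs, _ = lasso_path(Xs, Yc[:, k], alphas=alphas, tol=path_tol)
            coef_stack[order, :, k] = coefs.T
        return [result("mLASSO", coef_stack[i], {"lam": float(lams[i])})
                for i in range(len(grid))]

    # EN: group candidates by mixing level, warm-started path per group
    out: list = [None] * len(grid)
    groups: dict = {}
    for i, h in enumerate(grid):
        lam1, lam2 = h["lam1"], h["lam2"]
        if lam1 == 0 or lam2 == 0:
            out[i] = fit_method("EN", X, Y, h, options)
            continue
        a = lam2 / (2 * n)
        b = lam1 / (2 * n)
        alpha, ratio = a + 2 * b, a / (a + 2 * b)
        groups.setdefault(round(ratio, 12), []).append((i, alpha, lam1, lam2))
    for ratio, items in groups.items():
        idx = np.argsort([it[1] for it in items])[::-1]
        alphas = np.array([items[i][1] for i in idx])
        coef_stack = np.empty((len(items), Xs.shape[1], Yc.shape[1]))
        for k in range(Yc.shape[1]):
            _, coefs, _ = enet_path(Xs, Yc[:, k], alphas=alphas,
                                    l1_ratio=ratio, tol=path_tol)
            coef_stack[:, :, k] = coefs.T
        for pos, i_sorted in enumerate(idx):
            gi, _, lam1, lam2 = items[i_sorted]
            out[gi] = result("EN", coef_stack[pos],
                             {"lam1": float(lam1), "lam2": float(lam2)})
    return out
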