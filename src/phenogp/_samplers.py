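"""Numba-compiled Gibbs samplers for the Bayesian whole-genome regressions.

Both samplers use single-site (coordinate-wise) updates with running
residuals, which keeps a sweep at O(n p) (Bayesian LASSO) / O(n p t)
(multi-trait BayesB) and makes desk-scale chains fast on one CPU.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _rinvgauss(mu: float, lam: float) -> float:
    """Inverse-Gaussian draw (Michael-Schucany-Haas)."""
    v = np.random.normal()
    y = v * v
    x = (mu + mu * mu * y / (2.0 * lam)
         - (mu / (2.0 * lam)) * np.sqrt(4.0 * mu * lam * y + mu * mu * y * y))
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def bl_gibbs(X, y, n_iter, burn_in, seed, r_hyper, delta_hyper):
    """Bayesian LASSO Gibbs sampler (normal-exponential scale mixture).

    Conjugate updates for the intercept, each coefficient (single-site),
    the per-coefficient mixing variances tau2, the residual variance and
    the squared regularization parameter lambda2 (gamma hyperprior with
    shape r_hyper and rate delta_hyper).

    Returns (b_mean, mu_mean, sigma2_mean, lambda_mean, ok_flag).
    """
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    b = np.zeros(p)
    tau2 = np.ones(p)
    mu = y.mean()
    sigma2 = y.var() + 1e-8
    lambda2 = 1.0
    e = y - mu  # running residual (b = 0 initially)

    b_sum = np.zeros(p)
    mu_sum = 0.0
    s2_sum = 0.0
    lam_sum = 0.0
    kept = 0
    ok = True

    for it in range(n_iter):
        # intercept
        mu_new = (e.mean() + mu) + np.random.normal() * np.sqrt(sigma2 / n)
        e -= mu_new - mu
        mu = mu_new

        # coefficients, single-site
        for j in range(p):
            if xtx[j] <= 0.0:
                # zero column: posterior equals the prior, residual unaffected
                b[j] = np.random.normal() * np.sqrt(sigma2 * tau2[j])
                continue
            b_old = b[j]
            if b_old != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * b_old
            prec = xtx[j] + 1.0 / tau2[j]
            var_j = sigma2 / prec
            mean_j = 0.0
            for i in range(n):
                mean_j += X[i, j] * e[i]
            mean_j /= prec
            b_new = mean_j + np.random.normal() * np.sqrt(var_j)
            for i in range(n):
                e[i] -= X[i, j] * b_new
            b[j] = b_new

        # mixing variances
        for j in range(p):
            b2 = b[j] * b[j]
            if b2 < 1e-12:
                b2 = 1e-12
            inv_tau2 = _rinvgauss(np.sqrt(lambda2 * sigma2 / b2), lambda2)
            tau2[j] = 1.0 / inv_tau2

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        pen = 0.0
        for j in range(p):
            pen += b[j] * b[j] / tau2[j]
        shape = 0.5 * (n - 1 + p)
        rate = 0.5 * (sse + pen)
        sigma2 = 1.0 / np.random.gamma(shape, 1.0 / rate)

        # regularization parameter
        tsum = 0.0
        for j in range(p):
            tsum += tau2[j]
        lambda2 = np.random.gamma(p + r_hyper, 1.0 / (delta_hyper + 0.5 * tsum))

        if not (np.isfinite(sigma2) and np.isfinite(lambda2)):
            ok = False
            break

        if it >= burn_in:
            kept += 1
            mu_sum += mu
            s2_sum += sigma2
            lam_sum += np.sqrt(lambda2)
            for j in range(p):
                b_sum[j] += b[j]

    if kept == 0:
        ok = False
        kept = 1
    return b_sum / kept, mu_sum / kept, s2_sum / kept, lam_sum / kept, ok


@njit(cache=True)
def _chol_small(A: np.ndarray) -> np.ndarray:
    """Cholesky for small dense SPD matrices (loop form avoids LAPACK
    dispatch overhead inside per-locus loops)."""
    t = A.shape[0]
    L = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, i] = np.sqrt(s if s > 1e-12 else 1e-12)
            else:
                L[i, j] = s / L[j, j]
    return L


@njit(cache=True)
def _wishart(df: float, scale_chol: np.ndarray) -> np.ndarray:
    """Wishart draw via the Bartlett decomposition; scale_chol = chol(V)."""
    t = scale_chol.shape[0]
    A = np.zeros((t, t))
    for i in range(t):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.normal()
    L = scale_chol @ A
    return L @ L.T


@njit(cache=True)
def _inv_wishart(df: float, psi: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw with scale matrix psi."""
    psi_inv = np.linalg.inv(psi)
    # symmetrize before cholesky to absorb round-off
    psi_inv = 0.5 * (psi_inv + psi_inv.T)
    W = _wishart(df, _chol_small(psi_inv))
    out = np.linalg.inv(W)
    return 0.5 * (out + out.T)


@njit(cache=True)
def mbayesb_gibbs(X, Y, n_iter, burn_in, pi, nu, S_prior, nu_r, S_r_prior, seed):
    """Multi-trait BayesB Gibbs sampler.

    Each locus j carries a t-vector of inclusion indicators (any of the 2^t
    patterns) and a latent effect vector beta_j ~ N(0, Sigma_j) with a
    locus-specific covariance Sigma_j ~ IW(nu, S_prior).  The realized
    effect on trait k is delta_jk * beta_jk.  The residual covariance R has
    an IW(nu_r, S_r_prior) prior.  Indicators and effects are sampled
    jointly per (locus, trait) with the effect integrated out of the
    inclusion odds.  Only the locus precision Sigma_j^{-1} is stored (the
    conditional-prior updates never need Sigma_j itself) and all per-locus
    temporaries live in preallocated buffers.

    Returns (B_mean, incl_freq, mu_mean, ok_flag).
    """
    np.random.seed(seed)
    n, p = X.shape
    t = Y.shape[1]

    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    beta = np.zeros((p, t))
    delta = np.zeros((p, t), dtype=np.int64)
    Sp_inv = np.linalg.inv(S_prior)
    Sinv0 = Sp_inv * max(nu - t - 1.0, 1.0)
    Sinv = np.empty((p, t, t))
    for j in range(p):
        Sinv[j] = Sinv0
    mu = np.zeros(t)
    for k in range(t):
        mu[k] = Y[:, k].mean()
    E = Y - mu  # running residual (all effects 0 initially)
    R = np.eye(t)
    for k in range(t):
        R[k, k] = Y[:, k].var() + 1e-8
    C = np.linalg.inv(R)

    log_prior_odds = np.log(pi) - np.log(1.0 - pi) if pi < 1.0 else 1e10

    B_sum = np.zeros((p, t))
    incl_sum = np.zeros((p, t))
    mu_sum = np.zeros(t)
    kept = 0
    ok = True

    # preallocated per-locus workspaces
    w = np.zeros(t)
    sb = np.zeros(t)
    V = np.zeros((t, t))
    Lbuf = np.zeros((t, t))
    Abuf = np.zeros((t, t))
    Mbuf = np.zeros((t, t))

    for it in range(n_iter):
        # intercepts: mu | rest ~ N(mu + colmean(E), R/n)
        Lr = _chol_small(0.5 * (R + R.T) / n)
        z = np.empty(t)
        for k in range(t):
            z[k] = np.random.normal()
        shift = Lr @ z
        for k in range(t):
            m = 0.0
            for i in range(n):
                m += E[i, k]
            m /= n
            d = m + shift[k]
            mu[k] += d
            for i in range(n):
                E[i, k] -= d

        for j in range(p):
            if xtx[j] <= 0.0:
                continue
            # w[l] = x_j' E[:, l]
            for l in range(t):
                w[l] = 0.0
            for i in range(n):
                xij = X[i, j]
                if xij != 0.0:
                    for l in range(t):
                        w[l] += xij * E[i, l]
            for k in range(t):
                alpha_old = beta[j, k] if delta[j, k] == 1 else 0.0
                if alpha_old != 0.0:
                    for i in range(n):
                        E[i, k] += X[i, j] * alpha_old
                    w[k] += xtx[j] * alpha_old
                # conditional prior of beta_jk | beta_j,-k
                v = 1.0 / Sinv[j, k, k]
                m_pr = 0.0
                for l in range(t):
                    if l != k:
                        m_pr -= Sinv[j, k, l] * beta[j, l]
                m_pr *= v
                # data terms
                q = xtx[j] * C[k, k]
                r1 = 0.0
                for l in range(t):
                    r1 += C[k, l] * w[l]
                P = q + 1.0 / v
                m_post = (r1 + m_pr / v) / P
                log_bf = (0.5 * np.log(1.0 / (v * P))
                          + 0.5 * (m_post * m_post * P - m_pr * m_pr / v))
                logit = log_prior_odds + log_bf
                if logit > 35.0:
                    prob = 1.0
                elif logit < -35.0:
                    prob = 0.0
                else:
                    prob = 1.0 / (1.0 + np.exp(-logit))
                if np.random.random() < prob:
                    delta[j, k] = 1
                    b_new = m_post + np.random.normal() / np.sqrt(P)
                    beta[j, k] = b_new
                    for i in range(n):
                        E[i, k] -= X[i, j] * b_new
                    w[k] -= xtx[j] * b_new
                else:
                    delta[j, k] = 0
                    beta[j, k] = m_pr + np.random.normal() * np.sqrt(v)

            # locus precision ~ Wishart(nu + 1, inv(S_prior + bb'));
            # Sherman-Morrison gives the inverse scale in O(t^2) and the
            # Bartlett construction writes into the preallocated buffers
            dot_sb = 0.0
            for k in range(t):
                acc = 0.0
                for l in range(t):
                    acc += Sp_inv[k, l] * beta[j, l]
                sb[k] = acc
                dot_sb += beta[j, k] * acc
            denom = 1.0 + dot_sb
            for k in range(t):
                for l in range(t):
                    V[k, l] = Sp_inv[k, l] - sb[k] * sb[l] / denom
            # in-place cholesky of V into Lbuf
            for a in range(t):
                for c2 in range(a + 1):
                    acc = V[a, c2]
                    for c in range(c2):
                        acc -= Lbuf[a, c] * Lbuf[c2, c]
                    if a == c2:
                        Lbuf[a, a] = np.sqrt(acc if acc > 1e-12 else 1e-12)
                    else:
                        Lbuf[a, c2] = acc / Lbuf[c2, c2]
            # Bartlett factor into Abuf (lower triangular)
            for a in range(t):
                Abuf[a, a] = np.sqrt(np.random.chisquare(nu + 1.0 - a))
                for c2 in range(a):
                    Abuf[a, c2] = np.random.normal()
            # M = Lbuf @ Abuf (both lower triangular); Sinv[j] = M @ M'
            for a in range(t):
                for c2 in range(t):
                    acc = 0.0
                    if c2 <= a:
                        for c in range(c2, a + 1):
                            acc += Lbuf[a, c] * Abuf[c, c2]
                    Mbuf[a, c2] = acc
            for a in range(t):
                for c2 in range(a + 1):
                    acc = 0.0
                    for c in range(t):
                        acc += Mbuf[a, c] * Mbuf[c2, c]
                    Sinv[j, a, c2] = acc
                    Sinv[j, c2, a] = acc

        # residual covariance
        EtE = E.T @ E
        R = _inv_wishart(nu_r + n, S_r_prior + EtE)
        C = np.linalg.inv(R)
        C = 0.5 * (C + C.T)

        finite = True
        for k in range(t):
            if not np.isfinite(R[k, k]):
                finite = False
        if not finite:
            ok = False
            break

        if it >= burn_in:
            kept += 1
            for jj in range(p):
                for k in range(t):
                    if delta[jj, k] == 1:
                        B_sum[jj, k] += beta[jj, k]
                        incl_sum[jj, k] += 1.0
            for k in range(t):
                mu_sum[k] += mu[k]

    if kept == 0:
        ok = False
        kept = 1
    return B_sum / kept, incl_sum / kept, mu_sum / kept, ok
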