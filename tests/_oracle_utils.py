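"""Shared simulation oracles used by unit and acceptance tests.

These deliberately avoid the package's own fitting/covariance code paths:
the batched logistic fitter is an independent vectorized IRLS, and the
phenotype simulator here draws latent vectors directly from per-family
Cholesky factors.
"""

import numpy as np
from scipy.special import expit, ndtri

import nrvat


def true_null_fit(ped, X, gamma):
    """NullModelFit evaluated at the *true* gamma (oracle for Omega checks)."""
    from nrvat.core import NullModelFit

    X = np.asarray(X, float)
    mu = expit(X @ gamma)
    delta = mu * (1 - mu)
    I = ped.n_families
    A = (X.T * delta) @ X / I
    scores = np.zeros((I, X.shape[1]))
    return NullModelFit(gamma=np.asarray(gamma, float), mu=mu, delta=delta,
                        A=A, scores=scores, n_families=I, n_iter=0)


def simulate_setting1_batched(ped, mu, h2, n_rep, rng):
    """n_rep x N Gaussian-copula phenotype matrix for fixed margins mu."""
    N = ped.n_individuals
    Y = np.empty((n_rep, N), dtype=np.int8)
    thr = ndtri(mu)
    for fam, sl, psi in zip(ped.families, ped.family_slices(),
                            ped.relatedness_blocks()):
        L = np.linalg.cholesky(nrvat.copula_correlation(psi, h2))
        Z = (L @ rng.standard_normal((fam.size, n_rep))).T
        Y[:, sl] = Z <= thr[sl]
    return Y


def batched_logistic(Y, X, iters=10):
    """Vectorized Newton/IRLS over replicates (rows of Y); independent of the
    package's fitter."""
    B = Y.shape[0]
    p = X.shape[1]
    g = np.zeros((B, p))
    for _ in range(iters):
        mu = expit(g @ X.T)
        grad = (Y - mu) @ X
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = np.einsum("bn,ni,nj->bij", w, X, X)
        g += np.linalg.solve(H, grad[..., None])[..., 0]
    return g


def empirical_residual_covariance(ped, X, gamma, h2, n_rep, rng):
    """Raw second moment of Y - mu_hat over Setting-1 replicates at fixed X."""
    mu_true = expit(np.asarray(X, float) @ gamma)
    Y = simulate_setting1_batched(ped, mu_true, h2, n_rep, rng)
    gh = batched_logistic(Y.astype(float), np.asarray(X, float))
    resid = Y - expit(gh @ np.asarray(X, float).T)
    return resid.T @ resid / n_rep


def covariance_zscores(emp, omega, n_rep):
    """(empirical - omega) scaled by the MC standard error of each entry."""
    d = np.diag(omega)
    se = np.sqrt((np.outer(d, d) + omega**2) / n_rep)
    return (emp - omega) / se
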