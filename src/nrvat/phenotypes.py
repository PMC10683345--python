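"""Covariate, effect and binary-phenotype generation for family designs.

Four dependence mechanisms are provided.  The Gaussian-copula generator is
the model the association test assumes: marginal disease probabilities
mu_ij come from a logistic model, and a latent normal vector with
correlation Gamma_i = h2*Psi_i + (1-h2)*I couples relatives, so margins
are preserved exactly for any h2.  The GLMM, Student-t-copula and
chi-square-copula generators are the misspecification scenarios the test
is stressed against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .pedigree import Pedigree, copula_correlation

__all__ = [
    "EffectModel",
    "simulate_covariates",
    "draw_beta",
    "linear_predictor",
    "simulate_gaussian_copula",
    "simulate_glmm",
    "simulate_t_copula",
    "simulate_chisq_copula",
    "chisq_copula_uniform",
    "apply_missingness",
]

DEFAULT_GAMMA = np.array([-2.0, 1.0, 1.0])

_U_EPS = 1e-12  # guard before ndtri in the chi-square copula transform


@dataclass(frozen=True)
class EffectModel:
    """Random variant effects beta ~ N(0, tau * W) on a causal subset."""

    tau: float
    weights: np.ndarray
    causal_mask: np.ndarray

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0; got {self.tau}")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "causal_mask",
                           np.asarray(self.causal_mask, dtype=bool))

    @classmethod
    def random_causal(cls, tau: float, weights: np.ndarray, n_causal: int,
                      rng) -> "EffectModel":
        """Default design: n_causal variants chosen uniformly at random."""
        rng = np.random.default_rng(rng)
        r = len(weights)
        mask = np.zeros(r, dtype=bool)
        mask[rng.choice(r, size=n_causal, replace=False)] = True
        return cls(tau=tau, weights=weights, causal_mask=mask)


def simulate_covariates(ped: Pedigree, rng) -> np.ndarray:
    """N x 3 design matrix [1, X1 ~ U(0,1), X2 ~ Bernoulli(0.2)]."""
    rng = np.random.default_rng(rng)
    n = ped.n_individuals
    return np.column_stack([
        np.ones(n),
        rng.uniform(0.0, 1.0, size=n),
        (rng.random(n) < 0.2).astype(float),
    ])


def draw_beta(effect: EffectModel, rng) -> np.ndarray:
    """beta_l ~ independent N(0, tau * w_l) on the causal mask, 0 elsewhere."""
    rng = np.random.default_rng(rng)
    beta = np.zeros(len(effect.weights))
    m = effect.causal_mask
    beta[m] = rng.normal(0.0, np.sqrt(effect.tau * effect.weights[m]))
    return beta


def linear_predictor(X: np.ndarray, G: np.ndarray | None, gamma: np.ndarray,
                     beta: np.ndarray | None) -> np.ndarray:
    eta = X @ gamma
    if G is not None and beta is not None:
        eta = eta + G @ beta
    return eta


def _threshold(Z: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return (Z <= ndtri(mu)).astype(np.int8)


def _per_family_latent(ped: Pedigree, h2: float, rng, draw):
    """Stack per-family latent draws Z_i built from cholesky(Gamma_i)."""
    out = np.empty(ped.n_individuals)
    for fam, sl, psi in zip(ped.families, ped.family_slices(),
                            ped.relatedness_blocks()):
        L = np.linalg.cholesky(copula_correlation(psi, h2))
        out[sl] = draw(L, fam.size, rng)
    return out


def simulate_gaussian_copula(ped: Pedigree, X, G, gamma, beta, h2, rng) -> np.ndarray:
    """Gaussian-copula phenotypes: Y_ij = 1{Z_ij <= Phi^-1(mu_ij)}, Z_i ~ N(0, Gamma_i)."""
    rng = np.random.default_rng(rng)
    mu = expit(linear_predictor(X, G, gamma, beta))
    Z = _per_family_latent(
        ped, h2, rng, lambda L, n, rng: L @ rng.standard_normal(n)
    )
    return _threshold(Z, mu)


def simulate_glmm(ped: Pedigree, X, G, gamma, beta, h2, rng) -> np.ndarray:
    """GLMM phenotypes: logit(mu_i) = X_i gamma + G_i beta + b_i, b_i ~ N(0, h2*Psi_i)."""
    rng = np.random.default_rng(rng)
    eta = linear_predictor(X, G, gamma, beta)
    b = np.zeros(ped.n_individuals)
    if h2 > 0:
        for fam, sl, psi in zip(ped.families, ped.family_slices(),
                                ped.relatedness_blocks()):
            L = np.linalg.cholesky(psi)
            b[sl] = np.sqrt(h2) * (L @ rng.standard_normal(fam.size))
    return (rng.random(ped.n_individuals) < expit(eta + b)).astype(np.int8)


def simulate_t_copula(ped: Pedigree, X, G, gamma, beta, h2, rng, df: float = 3.0,
                      correct_margins: bool = False) -> np.ndarray:
    """Student-t latent phenotypes: Z_i ~ multivariate t(df) with correlation Gamma_i.

    By default the t variates are thresholded at Phi^-1(mu) directly, which
    deliberately distorts the margins to P(Y=1) = F_t(Phi^-1(mu)) — this is
    the misspecification stress scenario.  correct_margins=True applies
    the probability transform Phi^-1(F_t(Z)) first, giving a pure t-copula
    with exact logistic margins.
    """
    if df <= 0:
        raise ValueError(f"df must be > 0; got {df}")
    rng = np.random.default_rng(rng)
    mu = expit(linear_predictor(X, G, gamma, beta))
    Z = np.empty(ped.n_individuals)
    for fam, sl, psi in zip(ped.families, ped.family_slices(),
                            ped.relatedness_blocks()):
        L = np.linalg.cholesky(copula_correlation(psi, h2))
        g = L @ rng.standard_normal(fam.size)
        scale = np.sqrt(rng.chisquare(df) / df)  # one mixing draw per family
        Z[sl] = g / scale
    if correct_margins:
        from scipy.stats import t as t_dist

        Z = ndtri(np.clip(t_dist.cdf(Z, df), _U_EPS, 1 - _U_EPS))
    return _threshold(Z, mu)


def chisq_copula_uniform(z_tilde: np.ndarray, a: float) -> np.ndarray:
    """U = sign(z+a) * {Phi(z+2a) + Phi(z) - 1}, the chi-square copula transform.

    U is the CDF of (Z+a)^2 evaluated at the realized value, signed so it
    lands in [0, 1]; sign(0) := 0 gives U = 0 at z = -a (probability-zero
    event), clipped away from {0, 1} before any inverse-normal mapping.
    """
    if a < 0:
        raise ValueError(f"noncentrality a must be >= 0; got {a}")
    z = np.asarray(z_tilde, dtype=float)
    u = np.sign(z + a) * (ndtr(z + 2 * a) + ndtr(z) - 1.0)
    return np.clip(u, _U_EPS, 1.0 - _U_EPS)


def simulate_chisq_copula(ped: Pedigree, X, G, gamma, beta, h2, rng,
                          a: float = 1.0) -> np.ndarray:
    """Chi-square-copula phenotypes with noncentrality a (default 1)."""
    rng = np.random.default_rng(rng)
    mu = expit(linear_predictor(X, G, gamma, beta))
    Zt = _per_family_latent(
        ped, h2, rng, lambda L, n, rng: L @ rng.standard_normal(n)
    )
    Z = ndtri(chisq_copula_uniform(Zt, a))
    return _threshold(Z, mu)


# MAR default: masking logit-linear in the covariates with unit slopes,
# centred at the covariate means so the average rate stays near p
_MAR_SLOPES = np.array([1.0, 1.0])
_COVARIATE_MEANS = np.array([0.5, 0.2])


def apply_missingness(Y, X, G, mechanism: str, p: float, rng) -> np.ndarray:
    """Boolean mask of subjects to treat as missing (for listwise deletion).

    mechanism "mcar": each subject masked independently with probability p.
    mechanism "mar":  logit(P(miss)) = logit(p) + (X1 - 0.5) + (X2 - 0.2).
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"missingness rate must lie in [0, 1); got {p}")
    rng = np.random.default_rng(rng)
    n = len(Y)
    if p == 0.0:
        return np.zeros(n, dtype=bool)
    if mechanism == "mcar":
        prob = np.full(n, p)
    elif mechanism == "mar":
        logit_p = np.log(p / (1 - p))
        prob = expit(logit_p + (X[:, 1:3] - _COVARIATE_MEANS) @ _MAR_SLOPES)
    else:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    return rng.random(n) < prob
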