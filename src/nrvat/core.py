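"""The copula-based variant-set score test for binary traits in families.

Pipeline: fit the marginal logistic null model under working independence;
estimate the latent-scale polygenic heritability h2 by pairwise composite
likelihood over within-family relative pairs; build the residual
covariance Omega — Gaussian-copula family blocks Sigma_i corrected by the
sandwich terms that account for estimating gamma; form the quadratic score
statistic Q = (Y - mu)^T K (Y - mu); and obtain its p-value from the
weighted mixture-of-chi-square null, Q ~ sum_n theta_n chi2_1 with theta_n
the eigenvalues of Omega^{1/2} K Omega^{1/2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import expit, ndtri
from scipy.stats import ncx2

from ._bivnorm import bvn_cdf
from .genotypes import GenotypeSet, founder_maf
from .kernels import (KernelSpec, WeightSpec, kernel_matrix,
                      linear_kernel_factor, maf_weights)
from .pedigree import Pedigree, copula_correlation

__all__ = [
    "NullModelFit",
    "TestResult",
    "FitError",
    "EstimationError",
    "DegenerateTestError",
    "fit_null_logistic",
    "pair_prob",
    "estimate_h2",
    "sigma_block",
    "build_omega",
    "score_statistic",
    "pvalue_mixture_chisq",
    "mixture_chisq_sf",
    "nrvat_test",
    "nrvat_test_multi",
]

_CELL_FLOOR = 1e-12       # probability floor inside pairwise log-likelihood
_H2_UPPER = 1.0 - 1e-6    # open upper bound of the h2 search interval
_EIG_DROP = 1e-10         # relative cutoff for discarding tiny mixture weights
_P_FLOOR = 1e-16


class FitError(RuntimeError):
    """Null-model fitting failed (non-convergence, separation, singular A)."""


class EstimationError(RuntimeError):
    """Heritability cannot be estimated from the supplied pedigree."""


class DegenerateTestError(RuntimeError):
    """All mixture weights vanish (e.g. monomorphic region)."""


# ---------------------------------------------------------------------------
# null model


@dataclass
class NullModelFit:
    """Marginal logistic fit under working independence, plus sandwich blocks.

    delta is the vector mu*(1-mu) (the diagonal of Delta); A is the averaged
    information (1/I) sum_i X_i' Delta_i X_i; scores holds the per-family
    score vectors S_i = X_i'(Y_i - mu_i) used by the empirical B estimator.
    """

    gamma: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    A: np.ndarray
    scores: np.ndarray
    n_families: int
    n_iter: int
    h2: float | None = None


def fit_null_logistic(Y, X, ped: Pedigree) -> NullModelFit:
    """Maximize the working-independence logistic likelihood of Y on X.

    Newton/IRLS iterations from gamma = 0 until the score has sup-norm
    below 1e-8.  Raises FitError on (quasi-)separation or non-convergence
    and ValueError on a rank-deficient design.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(Y)) - {0.0, 1.0}:
        raise ValueError("Y must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X is rank deficient")
    gamma, n_iter = _newton_irls(Y, X)
    mu = expit(X @ gamma)
    if np.any(mu <= 1e-10) or np.any(mu >= 1 - 1e-10):
        raise FitError(
            "fitted probabilities at the 0/1 boundary: (quasi-)separation; "
            "remove the offending covariate or merge sparse categories"
        )
    delta = mu * (1.0 - mu)
    I = ped.n_families
    A = (X.T * delta) @ X / I
    resid = Y - mu
    scores = np.stack([X[sl].T @ resid[sl] for sl in ped.family_slices()])
    return NullModelFit(gamma=gamma, mu=mu, delta=delta, A=A, scores=scores,
                        n_families=I, n_iter=n_iter)


def _newton_irls(Y, X, tol: float = 1e-8, maxiter: int = 50):
    gamma = np.zeros(X.shape[1])
    for it in range(1, maxiter + 1):
        mu = expit(X @ gamma)
        grad = X.T @ (Y - mu)
        if np.max(np.abs(grad)) < tol:
            return gamma, it
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = (X.T * w) @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix in logistic fit") from exc
        # damp diverging steps (separation drives |gamma| to infinity)
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        gamma = gamma + step
        if np.max(np.abs(gamma)) > 40.0:
            raise FitError(
                "diverging coefficients in the null logistic model: "
                "perfect separation"
            )
    raise FitError("logistic score iterations did not converge")


# ---------------------------------------------------------------------------
# pairwise quantities


def pair_prob(mu_j, mu_k, rho):
    """P(Y_j = 1, Y_k = 1) under the Gaussian copula with latent correlation rho.

    Equals Phi2(Phi^-1(mu_j), Phi^-1(mu_k); rho).  Vectorized; |rho| must be
    strictly below 1.
    """
    mu_j = np.asarray(mu_j, dtype=float)
    mu_k = np.asarray(mu_k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("latent correlation must lie in (-1, 1)")
    if np.any((mu_j <= 0) | (mu_j >= 1) | (mu_k <= 0) | (mu_k >= 1)):
        raise ValueError("marginal probabilities must lie in (0, 1)")
    return bvn_cdf(ndtri(mu_j), ndtri(mu_k), rho)


@dataclass
class _PairIndex:
    """Within-family relative pairs flattened to global row indices."""

    j: np.ndarray
    k: np.ndarray
    psi: np.ndarray

    @classmethod
    def from_pedigree(cls, ped: Pedigree, psi_blocks=None) -> "_PairIndex":
        psi_blocks = psi_blocks or ped.relatedness_blocks()
        js, ks, ps = [], [], []
        for sl, psi in zip(ped.family_slices(), psi_blocks):
            n = psi.shape[0]
            jj, kk = np.triu_indices(n, k=1)
            js.append(jj + sl.start)
            ks.append(kk + sl.start)
            ps.append(psi[jj, kk])
        cat = lambda a: np.concatenate(a) if a else np.empty(0)
        return cls(j=cat(js).astype(int), k=cat(ks).astype(int), psi=cat(ps))


def _pairwise_loglik(h2, Y, q, mu, pairs: _PairIndex) -> float:
    rho = h2 * pairs.psi
    p11 = bvn_cdf(q[pairs.j], q[pairs.k], rho)
    yj, yk = Y[pairs.j], Y[pairs.k]
    mj, mk = mu[pairs.j], mu[pairs.k]
    cell = np.where(
        yj == 1,
        np.where(yk == 1, p11, mj - p11),
        np.where(yk == 1, mk - p11, 1.0 - mj - mk + p11),
    )
    # ordered double sum = 2 x unordered sum (constant factor, same argmax)
    return 2.0 * np.sum(np.log(np.clip(cell, _CELL_FLOOR, None)))


def estimate_h2(Y, mu, ped: Pedigree, psi_blocks=None, xatol: float = 1e-4) -> float:
    """Polygenic heritability by maximum pairwise composite likelihood.

    The likelihood of every within-family pair (Y_j, Y_k) is a 2x2 table
    built from the bivariate Gaussian copula with latent correlation
    h2 * Psi_jk; the sum of log bivariate terms is maximized over
    h2 in [0, 1) by bounded scalar search.
    """
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    pairs = _PairIndex.from_pedigree(ped, psi_blocks)
    if pairs.j.size == 0:
        raise EstimationError(
            "no within-family pairs: heritability cannot be estimated; "
            "supply a fixed h2"
        )
    if np.all(pairs.psi == 0):
        warnings.warn(
            "all relative pairs have zero relatedness; pairwise likelihood "
            "is flat in h2 — returning 0",
            stacklevel=2,
        )
        return 0.0
    q = ndtri(mu)
    res = minimize_scalar(
        lambda h2: -_pairwise_loglik(h2, Y, q, mu, pairs),
        bounds=(0.0, _H2_UPPER),
        method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# residual covariance


def sigma_block(mu_i: np.ndarray, gamma_i: np.ndarray) -> np.ndarray:
    """Family residual covariance: diag mu(1-mu); off-diag C_rho(mu_j,mu_k) - mu_j mu_k."""
    mu_i = np.asarray(mu_i, dtype=float)
    n = mu_i.size
    sig = np.diag(mu_i * (1.0 - mu_i))
    if n > 1:
        jj, kk = np.triu_indices(n, k=1)
        off = pair_prob(mu_i[jj], mu_i[kk], gamma_i[jj, kk]) - mu_i[jj] * mu_i[kk]
        sig[jj, kk] = off
        sig[kk, jj] = off
    return sig


def sigma_blocks_for(fit: NullModelFit, ped: Pedigree, h2: float,
                     psi_blocks=None) -> list[np.ndarray]:
    psi_blocks = psi_blocks or ped.relatedness_blocks()
    return [
        sigma_block(fit.mu[sl], copula_correlation(psi, h2))
        for sl, psi in zip(ped.family_slices(), psi_blocks)
    ]


def build_omega(fit: NullModelFit, sigma_blocks, X, ped: Pedigree,
                b_mode: str = "model") -> np.ndarray:
    """Sandwich covariance of the stacked null residuals Y - mu_hat.

    Diagonal blocks: Sigma_i - (1/I) Delta_i X_i A^-1 X_i' Sigma_i
                               - (1/I) Sigma_i X_i A^-1 X_i' Delta_i
                               + (1/I) Delta_i X_i A^-1 B A^-1 X_i' Delta_i,
    with the analogous cross-family blocks (no leading Sigma term).  The
    middle matrix B is either model-based, (1/I) sum_i X_i' Sigma_i X_i
    (default: uses the fitted copula), or the empirical score outer product
    (1/I) sum_i S_i S_i'.
    """
    X = np.asarray(X, dtype=float)
    N, _ = X.shape
    I = ped.n_families
    try:
        Ainv = np.linalg.inv(fit.A)
    except np.linalg.LinAlgError as exc:
        raise FitError("averaged information matrix A is singular") from exc

    D = fit.delta[:, None] * X
    C = np.empty_like(X)
    Sigma_bd = np.zeros((N, N))
    for sl, sig in zip(ped.family_slices(), sigma_blocks):
        C[sl] = sig @ X[sl]
        Sigma_bd[sl, sl] = sig

    if b_mode == "model":
        B = X.T @ C / I
    elif b_mode == "empirical":
        B = fit.scores.T @ fit.scores / I
    else:
        raise ValueError(f"unknown b_mode {b_mode!r}")

    DAC = D @ Ainv @ C.T / I
    omega = Sigma_bd - DAC - DAC.T + D @ (Ainv @ B @ Ainv) @ D.T / I
    return (omega + omega.T) / 2.0


# ---------------------------------------------------------------------------
# statistic and p-value


def score_statistic(Y, mu, K) -> tuple[float, float]:
    """Q = (Y-mu)' K (Y-mu), and the diagnostic trace term tr(K Delta).

    The trace term appears in the raw variance-component score derivative
    but has negligible variability and is dropped from the statistic; it is
    returned for diagnostics only.
    """
    e = np.asarray(Y, dtype=float) - np.asarray(mu, dtype=float)
    K = np.asarray(K, dtype=float)
    q = float(e @ K @ e)
    tr = float(np.diag(K) @ (mu * (1.0 - mu)))
    return q, tr


def _omega_sqrt(omega: np.ndarray):
    """Eigenfactorization of Omega with negative eigenvalues clipped at 0."""
    evals, V = np.linalg.eigh(omega)
    neg = evals < 0
    clip_mass = float(-evals[neg].sum())
    evals = np.clip(evals, 0.0, None)
    if clip_mass > 1e-3 * max(evals.sum(), np.finfo(float).tiny):
        warnings.warn(
            f"Omega indefinite beyond tolerance: clipped mass {clip_mass:.3g} "
            f"vs trace {evals.sum():.3g}",
            stacklevel=3,
        )
    return V, np.sqrt(evals), int(neg.sum()), clip_mass


def _mixture_weights(V, sqrt_l, K=None, kernel_factor=None) -> np.ndarray:
    if kernel_factor is not None:
        E = (sqrt_l[:, None] * V.T) @ np.asarray(kernel_factor, dtype=float)
        M = E.T @ E
    else:
        VK = V.T @ np.asarray(K, dtype=float) @ V
        M = sqrt_l[:, None] * VK * sqrt_l[None, :]
    theta = np.linalg.eigvalsh(M)[::-1]
    return theta


def mixture_chisq_sf(q: float, lam: np.ndarray) -> tuple[float, str]:
    """Tail probability P(sum_n lam_n chi2_1 > q).

    Primary route: exact inversion of the characteristic function (Imhof's
    integral) by adaptive quadrature; falls back to Liu's moment-matching
    noncentral-chi-square approximation when the quadrature is unreliable
    or the probability is below its resolution.  Returns (p, method).
    """
    lam = np.asarray(lam, dtype=float)
    if q <= 0:
        return 1.0, "exact"
    # the mixture law is scale-equivariant; normalizing by the largest
    # weight keeps the inversion integrand oscillating on an O(1) scale
    scale = lam.max()
    lam = lam / scale
    q = q / scale
    p, ok = _imhof_sf(q, lam)
    if ok and 1e-10 <= p <= 1.0:
        return min(p, 1.0), "imhof"
    return _liu_sf(q, lam), "liu"


def _imhof_sf(q, lam):
    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        if log_rho > 700.0:
            return 0.0
        return np.sin(theta) * np.exp(-log_rho) / u

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = quad(integrand, 0.0, np.inf, limit=500, epsabs=1e-11,
                   epsrel=1e-9, full_output=1)
    ok = len(out) == 3 and out[1] < 1e-8
    return 0.5 + out[0] / np.pi, ok


def _liu_sf(q, lam):
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2.0 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = c2 ** 3 / c3 ** 2
    t_star = (q - c1) / np.sqrt(2.0 * c2)
    return float(ncx2.sf(t_star * np.sqrt(2.0) * a + df + delta, df, delta))


def pvalue_mixture_chisq(Q: float, omega: np.ndarray, K: np.ndarray):
    """p-value of Q against the mixture-of-chi-square null defined by Omega and K.

    Mixture weights are the eigenvalues of S K S with S the symmetric
    square root of Omega (negative Omega eigenvalues clipped at 0);
    weights below 1e-10 of the largest are dropped.  Returns
    (p_value, theta, info).
    """
    V, sqrt_l, n_clipped, clip_mass = _omega_sqrt(np.asarray(omega, dtype=float))
    theta = _mixture_weights(V, sqrt_l, K=K)
    return _theta_to_p(Q, theta, n_clipped, clip_mass)


def _theta_to_p(Q, theta, n_clipped, clip_mass):
    trace = float(theta.sum())
    keep = theta > _EIG_DROP * max(theta.max(initial=0.0), 0.0)
    theta = theta[keep]
    if theta.size == 0:
        raise DegenerateTestError(
            "all mixture weights are ~0 (monomorphic or empty region)"
        )
    p, method = mixture_chisq_sf(Q, theta)
    p = float(np.clip(p, _P_FLOOR, 1.0))
    info = {"pvalue_method": method, "omega_clipped": n_clipped,
            "omega_clip_mass": clip_mass, "trace_k_omega": trace}
    return p, theta, info


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class TestResult:
    """Outcome of the variant-set test for one region."""

    set_id: str
    kernel: str
    weights: str
    r_effective: int
    Q: float
    p_value: float
    h2_hat: float
    eigenvalues: np.ndarray = field(repr=False)
    trace_k_delta: float = 0.0
    pvalue_method: str = "imhof"
    omega_clipped: int = 0
    omega_clip_mass: float = 0.0
    warnings: list[str] = field(default_factory=list)


def nrvat_test(Y, X, G, ped: Pedigree, kernel="linear", weights="beta",
               h2="auto", b_mode: str = "model", maf=None,
               set_id: str = "set1") -> TestResult:
    """Run the full variant-set association test for one region.

    kernel: a KernelSpec or one of "linear", "quadratic", "ibs", "gaussian",
    "polynomial".  weights: a WeightSpec, "beta" (Beta(1,25) of the founder
    MAF), "flat", or a custom positive vector.  h2: "auto" (pairwise
    composite likelihood) or a fixed value in [0, 1).  Listwise deletion of
    incomplete subjects must be applied upstream.
    """
    results = nrvat_test_multi(Y, X, G, ped, kernels=[kernel], weights=weights,
                               h2=h2, b_mode=b_mode, maf=maf, set_id=set_id)
    return next(iter(results.values()))


def nrvat_test_multi(Y, X, G, ped: Pedigree, kernels, weights="beta",
                     h2="auto", b_mode: str = "model", maf=None,
                     set_id: str = "set1") -> dict[str, TestResult]:
    """Test one region with several kernels, sharing the null fit, h2 and Omega.

    The null model, heritability estimate and residual covariance do not
    depend on the kernel, so computing them once makes multi-kernel scans
    (and the simulation experiments) several-fold cheaper.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if isinstance(G, GenotypeSet):
        G = G.dosages
    G = np.asarray(G, dtype=float)
    notes: list[str] = []
    if ped.n_families < 30:
        notes.append(
            f"only {ped.n_families} families; asymptotic p-values may be unreliable"
        )

    if maf is None:
        fmask = np.array(
            [m.is_founder for fam in ped.families for m in fam.members], dtype=bool
        )
        maf = G[fmask].mean(axis=0) / 2.0
    maf = np.asarray(maf, dtype=float)
    maf = np.minimum(maf, 1.0 - maf)  # fold: weights use the minor allele
    poly = maf > 0
    if not np.all(poly):
        notes.append(f"dropped {int((~poly).sum())} monomorphic variant(s)")
        G = G[:, poly]
        maf = maf[poly]
    if G.shape[1] == 0:
        raise DegenerateTestError(f"{set_id}: no polymorphic variants")

    wspec = _resolve_weights(weights, maf)
    fit = fit_null_logistic(Y, X, ped)
    psi_blocks = ped.relatedness_blocks()
    if h2 == "auto":
        h2_hat = estimate_h2(Y, fit.mu, ped, psi_blocks)
    else:
        h2_hat = float(h2)
        if not 0.0 <= h2_hat < 1.0:
            raise ValueError(f"fixed h2 must lie in [0, 1); got {h2_hat}")
    fit.h2 = h2_hat

    sig = sigma_blocks_for(fit, ped, h2_hat, psi_blocks)
    omega = build_omega(fit, sig, X, ped, b_mode=b_mode)
    # the Omega^(1/2) K Omega^(1/2) spectrum is only needed explicitly for
    # dense kernels; for the rank-r linear kernel K = L L' the same nonzero
    # weights are the eigenvalues of the r x r matrix L' Omega L, which
    # skips the N x N eigendecomposition entirely
    sqrt_parts = None
    n_clipped = clip_mass = 0

    resid = Y - fit.mu
    out: dict[str, TestResult] = {}
    for kern in kernels:
        spec = kern if isinstance(kern, KernelSpec) else KernelSpec(kind=kern)
        if spec.kind == "linear":
            L = linear_kernel_factor(G, wspec)
            Q = float(np.sum((L.T @ resid) ** 2))
            tr = float((L * L).sum(axis=1) @ (fit.mu * (1 - fit.mu)))
            theta = np.linalg.eigvalsh(L.T @ omega @ L)[::-1]
        else:
            if sqrt_parts is None:
                sqrt_parts = _omega_sqrt(omega)
                n_clipped, clip_mass = sqrt_parts[2], sqrt_parts[3]
            K = kernel_matrix(G, wspec, spec)
            Q, tr = score_statistic(Y, fit.mu, K)
            theta = _mixture_weights(sqrt_parts[0], sqrt_parts[1], K=K)
        p, theta, info = _theta_to_p(Q, theta, n_clipped, clip_mass)
        out[spec.kind] = TestResult(
            set_id=set_id, kernel=spec.kind, weights=wspec.scheme,
            r_effective=G.shape[1], Q=Q, p_value=p, h2_hat=h2_hat,
            eigenvalues=theta, trace_k_delta=tr,
            pvalue_method=info["pvalue_method"], omega_clipped=n_clipped,
            omega_clip_mass=clip_mass, warnings=list(notes),
        )
    return out


def _resolve_weights(weights, maf) -> WeightSpec:
    if isinstance(weights, WeightSpec):
        return weights
    if isinstance(weights, str):
        return maf_weights(maf, scheme=weights)
    return WeightSpec("custom", np.asarray(weights, dtype=float))
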