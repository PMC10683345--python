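"""Per-variant weights and genotype-similarity kernel matrices.

Five kernels are supported: linear (the canonical weighted cross-product
sum_l w_l G_ul G_vl), quadratic, IBS, Gaussian and polynomial.  Weights
default to the Beta(1, 25) density of the MAF, the standard rare-variant
up-weighting; each weight enters the kernel once (w_l, not w_l^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

__all__ = ["WeightSpec", "KernelSpec", "maf_weights", "kernel_matrix",
           "KERNEL_KINDS"]

KERNEL_KINDS = ("linear", "quadratic", "ibs", "gaussian", "polynomial")


@dataclass(frozen=True)
class WeightSpec:
    scheme: str
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and strictly positive")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind and parameters.

    bandwidth: Gaussian kernel scale; defaults to r (number of variants).
    degree/offset: polynomial kernel parameters (offset also used by the
    quadratic kernel, which is polynomial with degree 2).
    """

    kind: str = "linear"
    bandwidth: float | None = None
    degree: int = 3
    offset: float = 1.0

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(
                f"unknown kernel {self.kind!r}; choose from {KERNEL_KINDS}"
            )


def maf_weights(maf: np.ndarray, scheme: str = "beta", a1: float = 1.0,
                a2: float = 25.0) -> WeightSpec:
    """MAF-based variant weights.

    "beta": w_l = Beta(a1, a2) density at MAF_l (default Beta(1, 25), i.e.
    25 (1 - m)^24, sharply up-weighting rare variants).  "flat": w_l = 1.
    Monomorphic variants (MAF 0) must be filtered before weighting.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]; filter monomorphic variants")
    if scheme == "flat":
        return WeightSpec("flat", np.ones_like(maf))
    if scheme == "beta":
        return WeightSpec(f"beta({a1:g},{a2:g})", beta_dist.pdf(maf, a1, a2))
    raise ValueError(f"unknown weight scheme {scheme!r}")


def linear_kernel_factor(G: np.ndarray, w: WeightSpec) -> np.ndarray:
    """L with K_linear = L L^T; exposes the rank-r structure for fast spectra."""
    return np.asarray(G, dtype=float) * np.sqrt(w.weights)


def kernel_matrix(G: np.ndarray, w: WeightSpec, spec: KernelSpec) -> np.ndarray:
    """N x N kernel similarity matrix for dosage matrix G (no missing values)."""
    G = np.asarray(G, dtype=float)
    n, r = G.shape
    wt = w.weights
    if wt.shape != (r,):
        raise ValueError(f"weights length {wt.shape} does not match r={r}")

    if spec.kind in ("linear", "quadratic", "polynomial"):
        cross = (G * wt) @ G.T
        if spec.kind == "linear":
            K = cross
        else:
            deg = 2 if spec.kind == "quadratic" else spec.degree
            K = (spec.offset + cross) ** deg
    elif spec.kind == "ibs":
        # sum_l w_l (2 - |a - b|) with |a-b| = a + b - 2*min(a,b) and
        # min(a,b) = 1{a>=1}1{b>=1} + 1{a>=2}1{b>=2} for dosages in {0,1,2}
        a1 = (G >= 1).astype(float)
        a2 = (G >= 2).astype(float)
        mins = (a1 * wt) @ a1.T + (a2 * wt) @ a2.T
        u = G @ wt
        K = 2.0 * wt.sum() - (u[:, None] + u[None, :]) + 2.0 * mins
    elif spec.kind == "gaussian":
        bw = spec.bandwidth if spec.bandwidth is not None else float(r)
        sq = (G * G) @ wt
        d2 = sq[:, None] + sq[None, :] - 2.0 * (G * wt) @ G.T
        K = np.exp(-np.maximum(d2, 0.0) / bw)
    else:  # pragma: no cover - guarded in KernelSpec
        raise ValueError(f"unknown kernel {spec.kind!r}")
    return (K + K.T) / 2.0
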