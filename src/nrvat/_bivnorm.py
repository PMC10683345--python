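"""Vectorized bivariate standard-normal CDF.

Uses the classical Owen's-T identity

    Phi2(h, k; rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta

with a_h = (k - rho*h) / (h * sqrt(1 - rho^2)) (and symmetrically a_k),
beta = 1/2 when h*k < 0 (or one argument is zero and the other negative),
0 otherwise.  scipy.special.owens_t is a fast elementwise ufunc, so the
whole computation vectorizes over thousands of (h, k, rho) triples with
per-element accuracy near machine precision — needed because the pairwise
composite likelihood evaluates this for every relative pair at every
optimizer iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf"]

# exact zeros of h or k make a_h/a_k indeterminate; nudging them by an
# amount far below the CDF's curvature scale keeps the formula smooth
_ZERO_NUDGE = 1e-13
_RHO_EDGE = 1.0 - 1e-12


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    All three arguments broadcast elementwise.  |rho| may not exceed 1;
    values within 1e-12 of +/-1 are evaluated by the comonotone /
    antimonotone limits.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1.0):
        raise ValueError("correlation must lie in [-1, 1]")
    h, k, rho = np.broadcast_arrays(h, k, rho)
    h = np.where(h == 0.0, _ZERO_NUDGE, h)
    k = np.where(k == 0.0, _ZERO_NUDGE, k)

    # general-case formula evaluated with rho pulled just inside (-1, 1);
    # the exact-edge cases are overwritten below
    rho_c = np.clip(rho, -_RHO_EDGE, _RHO_EDGE)
    denom = np.sqrt(1.0 - rho_c * rho_c)
    a_h = (k - rho_c * h) / (h * denom)
    a_k = (h - rho_c * k) / (k * denom)
    beta = np.where(h * k < 0.0, 0.5, 0.0)
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta

    upper = rho >= _RHO_EDGE
    lower = rho <= -_RHO_EDGE
    if np.any(upper):
        val = np.where(upper, ndtr(np.minimum(h, k)), val)
    if np.any(lower):
        val = np.where(lower, np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0), val)
    return np.clip(val, 0.0, 1.0) if val.ndim else float(np.clip(val, 0.0, 1.0))
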