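"""Shared numerical helpers: link functions and finite-difference Hessians."""
from __future__ import annotations

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (re-exported)


def numeric_hessian(fun, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``x``.

    Step is scaled by max(1, |x_i|) per coordinate so that the estimate stays
    usable for parameters drifting toward a boundary on the link scale.
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def safe_vcov(neg_hessian_fun, x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert the observed information; fall back to pseudo-inverse.

    Returns (vcov, ok) where ok is False when the Hessian was singular or the
    resulting covariance had negative diagonal entries.
    """
    hess = numeric_hessian(neg_hessian_fun, x)
    ok = True
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(hess)
        ok = False
    vcov = 0.5 * (vcov + vcov.T)
    if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
        ok = False
    return vcov, ok


def numeric_gradient(fun, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.empty(x.size)
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(x.size):
        e = np.zeros(x.size)
        e[i] = h[i]
        g[i] = (fun(x + e) - fun(x - e)) / (2.0 * h[i])
    return g
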