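"""Gaussian-process building blocks: Matern covariance, AR1 structure, sampling.

The space-time residual model used both generatively (synthetic worlds) and
in inference is separable: a Matern spatial covariance across pixel centres
multiplied by a stationary first-order autoregression across the estimation
periods.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def matern_cov(d: np.ndarray, range_km: float, sd: float, nu: float = 1.5) -> np.ndarray:
    """Matern covariance at distances ``d`` (km).

    ``range_km`` follows the common geostatistical convention of the distance
    at which correlation drops to ~0.1: kappa = sqrt(8 nu) / range.
    """
    if range_km <= 0 or sd < 0:
        raise ValueError("range must be > 0 and sd >= 0")
    kappa = np.sqrt(8.0 * nu) / range_km
    h = kappa * np.asarray(d, dtype=float)
    if nu == 0.5:
        corr = np.exp(-h)
    elif nu == 1.5:
        corr = (1.0 + h) * np.exp(-h)
    elif nu == 2.5:
        corr = (1.0 + h + h**2 / 3.0) * np.exp(-h)
    else:
        raise ValueError(f"unsupported Matern smoothness nu={nu}")
    return sd**2 * corr


def matern_cov_xy(
    a: np.ndarray, b: np.ndarray, range_km: float, sd: float, nu: float = 1.5
) -> np.ndarray:
    """Cross-covariance between coordinate arrays ``a`` (n,2) and ``b`` (m,2)."""
    return matern_cov(cdist(a, b), range_km, sd, nu)


def ar1_corr(n: int, rho: float) -> np.ndarray:
    """Stationary AR1 correlation matrix of size n."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"AR1 rho must be in (-1, 1), got {rho}")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_precision(n: int, rho: float) -> np.ndarray:
    """Inverse of the stationary AR1 correlation matrix (tridiagonal)."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"AR1 rho must be in (-1, 1), got {rho}")
    q = np.zeros((n, n))
    if n == 1:
        q[0, 0] = 1.0
        return q
    s = 1.0 / (1.0 - rho**2)
    for i in range(n):
        q[i, i] = s * (1.0 + rho**2) if 0 < i < n - 1 else s
    for i in range(n - 1):
        q[i, i + 1] = q[i + 1, i] = -s * rho
    return q


def chol_psd(cov: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Cholesky factor with escalating jitter for near-singular covariances."""
    n = cov.shape[0]
    scale = float(np.mean(np.diag(cov))) or 1.0
    for k in range(8):
        try:
            return np.linalg.cholesky(cov + jitter * (10.0**k) * scale * np.eye(n))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not positive definite even with jitter")


def sample_matern_ar1(
    coords: np.ndarray,
    n_periods: int,
    range_km: float,
    sd: float,
    rho: float,
    rng: np.random.Generator,
    nu: float = 1.5,
    chol: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a separable Matern x AR1 field at ``coords`` over ``n_periods``.

    Returns an array (n_periods, n_points) with stationary AR1 dynamics so
    each period has the full Matern marginal covariance. Passing a
    precomputed spatial Cholesky factor ``chol`` skips the factorization.
    """
    n = coords.shape[0]
    if sd == 0.0:
        return np.zeros((n_periods, n))
    if chol is None:
        chol = chol_psd(matern_cov_xy(coords, coords, range_km, sd, nu))
    z = np.empty((n_periods, n))
    z[0] = chol @ rng.standard_normal(n)
    innov_scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n_periods):
        z[t] = rho * z[t - 1] + innov_scale * (chol @ rng.standard_normal(n))
    return z
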