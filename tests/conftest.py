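"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: the
steady-state gain is obtained by iterating the Riccati recursion, and the
Kalman posterior means are checked against a brute-force Bayesian filter on
a discretized state grid (Gaussian transition convolution + Gaussian
likelihood, posterior mean by quadrature).
"""

from __future__ import annotations

import numpy as np
import pytest

from respercept import Protocol


@pytest.fixture
def protocol() -> Protocol:
    return Protocol()


def riccati_fixed_point_gain(rho: float, p0: float = 1000.0) -> float:
    """Iterate P <- (1 - K)(P + 1), K = (P + 1)/(P + 1 + rho) to
    convergence and return the limiting gain."""
    p = p0
    k = np.nan
    for _ in range(10_000):
        m = p + 1.0
        k = m / (m + rho)
        p_new = (1.0 - k) * m
        if abs(p_new - p) < 1e-15:
            p = p_new
            break
        p = p_new
    return k


def grid_bayes_filter(
    y: np.ndarray,
    rho: float,
    init_mean: float,
    init_var: float,
    n_grid: int = 4801,
    pad: float = 12.0,
) -> np.ndarray:
    """Brute-force scalar Bayesian filter on a discretized state space.

    Random-walk transition N(0, 1) applied by dense convolution, Gaussian
    likelihood with variance rho, posterior mean by quadrature.  Returns
    the per-step posterior means.
    """
    y = np.asarray(y, dtype=float)
    lo = y.min() - pad
    hi = y.max() + pad
    c = np.linspace(lo, hi, n_grid)
    trans = np.exp(-0.5 * (c[:, None] - c[None, :]) ** 2)
    trans /= trans.sum(axis=0, keepdims=True)
    if init_var > 0:
        p = np.exp(-0.5 * (c - init_mean) ** 2 / init_var)
    else:
        p = np.zeros_like(c)
        p[np.argmin(np.abs(c - init_mean))] = 1.0
    p /= p.sum()
    means = np.empty_like(y)
    for t in range(y.size):
        p = trans @ p
        p = p * np.exp(-0.5 * (y[t] - c) ** 2 / rho)
        p /= p.sum()
        means[t] = float(np.dot(c, p))
    return means
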