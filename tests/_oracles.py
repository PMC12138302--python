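"""Independent oracles used by the test suite.

These deliberately avoid the package's own filtering code paths: the
joint-Gaussian construction builds the implied n x n covariance of the
observations explicitly and evaluates the density with scipy, and the
state-space simulator iterates the model equations directly.
"""

import numpy as np
from scipy.stats import multivariate_normal


def brute_force_loglik(y, Z, T, RQR, h, a0, P0):
    """Log-density of the observed entries of y under the state-space model,
    via the explicit joint multivariate-Gaussian construction."""
    n = len(y)
    means = [np.asarray(a0, dtype=float)]
    for _ in range(1, n):
        means.append(T @ means[-1])
    V = [[None] * n for _ in range(n)]
    V[0][0] = np.asarray(P0, dtype=float)
    for t in range(1, n):
        V[t][t] = T @ V[t - 1][t - 1] @ T.T + RQR
    for t in range(n):
        for s in range(t + 1, n):
            V[t][s] = V[t][s - 1] @ T.T
    mu_y = np.array([Z @ mv for mv in means])
    Sig = np.empty((n, n))
    for t in range(n):
        for s in range(n):
            block = V[t][s] if s >= t else V[s][t].T
            Sig[t, s] = Z @ block @ Z + (h if t == s else 0.0)
    obs = ~np.isnan(np.asarray(y, dtype=float))
    return float(
        multivariate_normal.logpdf(
            np.asarray(y)[obs], mu_y[obs], Sig[np.ix_(obs, obs)]
        )
    )


def simulate_bsts(n, sigma_eps, sigma_level, sigma_slope, sigma_seas, seed,
                  level0=6000.0, slope0=0.0, season_scale=200.0, period=7):
    """Iterate the trend + seasonal state equations directly."""
    rng = np.random.default_rng(seed)
    mu, delta = level0, slope0
    gamma = rng.normal(0.0, season_scale, period - 1)
    gamma = gamma - gamma.mean()
    y = np.empty(n)
    for t in range(n):
        y[t] = mu + gamma[0] + rng.normal(0.0, sigma_eps)
        mu = mu + delta + rng.normal(0.0, sigma_level)
        delta = delta + rng.normal(0.0, sigma_slope)
        new = -gamma.sum() + rng.normal(0.0, sigma_seas)
        gamma = np.concatenate(([new], gamma[:-1]))
    return y
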