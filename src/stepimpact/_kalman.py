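"""Numba kernels for linear-Gaussian state-space filtering and sampling.

These are the hot loops of the BSTS engine: a univariate-observation Kalman
filter (missing observations skipped) and a Carter-Kohn forward-filter
backward-sampler used as the simulation smoother inside the Gibbs sampler.
Standard-normal innovations are generated by the caller and passed in, so the
kernels themselves are free of RNG state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = 1.8378770664093453
# jitter added before Cholesky/inversion; state is on the standardized scale
_JITTER = 1e-12


@njit(cache=True)
def kalman_filter(y, observed, Z, T, RQR, h, a0, P0):
    """Kalman filter for y_t = Z'a_t + eps, a_{t+1} = T a_t + eta.

    Parameters are time-invariant; ``h`` is the observation-noise variance
    and ``RQR`` the state-noise covariance R Q R'. ``observed`` masks missing
    days, which contribute a prediction step but no update and no likelihood
    term.

    Returns (loglik, a_filt, P_filt, a_pred, P_pred) where ``a_pred[t]`` /
    ``P_pred[t]`` are the one-step-ahead moments of the state at time t.
    """
    n = y.shape[0]
    m = a0.shape[0]
    a_pred = np.empty((n, m))
    P_pred = np.empty((n, m, m))
    a_filt = np.empty((n, m))
    P_filt = np.empty((n, m, m))
    a = a0.copy()
    P = P0.copy()
    ll = 0.0
    for t in range(n):
        a_pred[t] = a
        P_pred[t] = P
        if observed[t]:
            PZ = P @ Z
            f = Z @ PZ + h
            v = y[t] - Z @ a
            ll += -0.5 * (_LOG2PI + np.log(f) + v * v / f)
            K = PZ / f
            a = a + K * v
            P = P - np.outer(K, PZ)
            P = 0.5 * (P + P.T)
        a_filt[t] = a
        P_filt[t] = P
        a = T @ a
        P = T @ P @ T.T + RQR
        P = 0.5 * (P + P.T)
    return ll, a_filt, P_filt, a_pred, P_pred


@njit(cache=True)
def _chol_lower(A, L):
    """In-place lower Cholesky; returns False instead of raising on non-PD."""
    m = A.shape[0]
    for i in range(m):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _safe_cholesky(A):
    """Cholesky with scale-adaptive jitter.

    Filtered covariances inherit roundoff of the order eps * ||P0|| from the
    approximate-diffuse initialization, which can leave tiny negative
    eigenvalues; the jitter is sized to the matrix's own diagonal scale.
    """
    m = A.shape[0]
    scale = 0.0
    for i in range(m):
        d = abs(A[i, i])
        if d > scale:
            scale = d
    # base jitter ~ accumulated roundoff (eps * scale * #ops); it must stay
    # far below the smallest state-noise variance or it biases the sampled
    # disturbances, so start tiny and escalate only on failure
    jit = 1e-14 * scale + _JITTER
    L = np.zeros((m, m))
    eye = np.eye(m)
    for _ in range(20):
        if _chol_lower(A + jit * eye, L):
            return L
        jit *= 10.0
    return L


@njit(cache=True)
def ffbs(a_filt, P_filt, a_pred, P_pred, T, normals):
    """Carter-Kohn backward sampler: one joint draw of the state path.

    ``normals`` is an (n, m) array of iid N(0,1) variates supplied by the
    caller. Conditional covariances can be singular when state variances are
    zero, so a scale-adaptive jitter keeps the Cholesky factorizations
    defined.
    """
    n, m = a_filt.shape
    eye = np.eye(m)
    alpha = np.empty((n, m))
    L = _safe_cholesky(P_filt[n - 1])
    alpha[n - 1] = a_filt[n - 1] + L @ normals[n - 1]
    for t in range(n - 2, -1, -1):
        G = P_filt[t] @ T.T
        scale = 0.0
        for i in range(m):
            d = abs(P_pred[t + 1, i, i])
            if d > scale:
                scale = d
        J = G @ np.linalg.inv(P_pred[t + 1] + (1e-12 * scale + _JITTER) * eye)
        mean = a_filt[t] + J @ (alpha[t + 1] - a_pred[t + 1])
        cov = P_filt[t] - J @ G.T
        cov = 0.5 * (cov + cov.T)
        L = _safe_cholesky(cov)
        alpha[t] = mean + L @ normals[t]
    return alpha
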