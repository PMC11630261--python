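"""Scaled forward-backward and Viterbi kernels, JIT-compiled with numba.

All kernels work on one observation sequence; emission likelihoods B (T x K)
are precomputed by the caller.  Scaling constants keep the recursion in
linear space without underflow; the log-likelihood is the sum of log scale
factors, so results are bit-identical for identical inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(B, pi, A):
    """Return (log_likelihood, alpha_hat, c) for one sequence."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    return np.log(c).sum(), alpha, c


@njit(cache=True)
def backward_scaled(B, A, c):
    """Scaled backward variables matching :func:`forward_scaled`'s scaling."""
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


@njit(cache=True)
def forward_backward(B, pi, A):
    """One E-step on one sequence.

    Returns (loglik, gamma, xi_sum, gamma0) where gamma is T x K posterior
    marginals, xi_sum the K x K expected transition counts and gamma0 the
    posterior at the first position.
    """
    T, K = B.shape
    ll, alpha, c = forward_scaled(B, pi, A)
    beta = backward_scaled(B, A, c)
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        w = B[t + 1] * beta[t + 1]
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += alpha[t, i] * A[i, j] * w[j] / c[t + 1]
    return ll, gamma, xi_sum, gamma[0].copy()


@njit(cache=True)
def viterbi_path(logB, logpi, logA):
    """Most probable state path for one sequence (log-space)."""
    T, K = logB.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    delta[0] = logpi + logB[0]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, delta[T - 1, path[T - 1]]
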