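"""Numba kernels for the sequential recursions.

Only code that is inherently a per-position loop lives here (HMM
forward/backward and strand cross-correlation pair counting); everything
else in the package is vectorised numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(nogil=True)
def forward_backward_kernel(pi, A, B):
    """Scaled forward-backward for one chain.

    Parameters
    ----------
    pi : (K,) initial distribution
    A : (K, K) row-stochastic transition matrix
    B : (T, K) emission likelihoods, each row rescaled so its max is 1
        (the caller accounts for the row offsets in the log-likelihood)

    Returns
    -------
    gamma : (T, K) posterior state probabilities
    xi_sum : (K, K) expected transition counts summed over t
    log_c : float, sum of log scaling factors (log-likelihood up to the
        caller's emission offsets)
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)

    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s

    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (
                    alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )

    gamma = alpha * beta
    # normalise defensively against fp drift
    for t in range(T):
        s = 0.0
        for k in range(K):
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    log_c = 0.0
    for t in range(T):
        log_c += np.log(c[t])
    return gamma, xi_sum, log_c


@njit(nogil=True)
def cross_correlation_counts(plus_pos, plus_cnt, minus_pos, minus_cnt, d_max):
    """Sum over tag pairs of count products, binned by strand offset.

    ``plus_pos``/``minus_pos`` are sorted unique per-base positions with
    multiplicities ``plus_cnt``/``minus_cnt``. Returns ``cross`` of length
    ``d_max + 1`` where ``cross[d] = sum_p plus[p] * minus[p + d]``.
    """
    cross = np.zeros(d_max + 1)
    n_plus = plus_pos.shape[0]
    lo = 0
    for j in range(minus_pos.shape[0]):
        pm = minus_pos[j]
        while lo < n_plus and plus_pos[lo] < pm - d_max:
            lo += 1
        i = lo
        while i < n_plus and plus_pos[i] <= pm:
            cross[pm - plus_pos[i]] += plus_cnt[i] * minus_cnt[j]
            i += 1
    return cross
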