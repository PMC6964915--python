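"""JIT-compiled per-trial recursions of the learning models.

These kernels return the trial-wise mean conditioned response (the model's
pre-outcome prediction) for a whole cue-outcome sequence, and exist because
maximum-likelihood fitting evaluates the recursions thousands of times per
dataset. The readable single-step implementations in :mod:`condesign.models`
are the reference; the test suite asserts both paths agree.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rw_means(X, r, alpha, w0):
    n, k = X.shape
    w = np.full(k, w0)
    m = np.empty(n)
    for t in range(n):
        x = X[t]
        pred = 0.0
        for j in range(k):
            pred += x[j] * w[j]
        m[t] = pred
        delta = r[t] - pred
        for j in range(k):
            w[j] += alpha * delta * x[j]
    return m


@njit(cache=True)
def krw_means(X, r, w0_mean, w0_var, q, r_noise_var):
    n, k = X.shape
    w = np.full(k, w0_mean)
    S = np.eye(k) * w0_var
    m = np.empty(n)
    for t in range(n):
        x = X[t]
        # weight diffusion between trials
        for j in range(k):
            S[j, j] += q
        pred = 0.0
        for j in range(k):
            pred += x[j] * w[j]
        m[t] = pred
        Sx = S @ x
        denom = x @ Sx + r_noise_var
        gain = Sx / denom
        delta = r[t] - pred
        for j in range(k):
            w[j] += gain[j] * delta
        S -= np.outer(gain, Sx)
        # keep symmetric against round-off
        for a in range(k):
            for b in range(a + 1, k):
                s = 0.5 * (S[a, b] + S[b, a])
                S[a, b] = s
                S[b, a] = s
    return m


@njit(cache=True)
def rwph_means(X, r, kappa, eta, alpha0, omega, mapping):
    """mapping: 0 -> weights V, 1 -> associabilities alpha, 2 -> mixture."""
    n, k = X.shape
    V = np.zeros(k)
    assoc = np.full(k, alpha0)
    m = np.empty(n)
    for t in range(n):
        x = X[t]
        pv = 0.0
        pa = 0.0
        for j in range(k):
            pv += x[j] * V[j]
            pa += x[j] * assoc[j]
        if mapping == 0:
            m[t] = pv
        elif mapping == 1:
            m[t] = pa
        else:
            m[t] = (1.0 - omega) * pv + omega * pa
        delta = r[t] - pv
        for j in range(k):
            if x[j] != 0.0:
                V[j] += kappa * assoc[j] * delta * x[j]
                assoc[j] = eta * abs(delta) + (1.0 - eta) * assoc[j]
    return m
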