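"""Compiled scalar-state Langevin particle filter.

For models with one latent component, scalar linear observation
y = p0 x + eps and Langevin dynamics — the configuration sitting inside the
heaviest MCMC loops — the whole filter runs as one numba kernel.  The
dynamics enter through a compiled ``moments(X, c, kappa, t) -> (a, G)``
hook returning the drift and diffusion covariance arrays over particles.
The arithmetic (weights, systematic resampling with pre-sorting, guided
bridge proposal) mirrors the generic numpy implementation in
:mod:`ssmem.filters` exactly; a test pins the two paths together.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LOG2PI = math.log(2.0 * math.pi)


@njit(nogil=True)
def _systematic(W, u01):
    N = W.shape[0]
    idx = np.empty(N, dtype=np.int64)
    cum = np.cumsum(W)
    cum[N - 1] = 1.0
    j = 0
    for n in range(N):
        pos = (u01 + n) / N
        while cum[j] < pos and j < N - 1:
            j += 1
        idx[n] = j
    return idx


@njit(nogil=True)
def pf_d1_kernel(
    moments, x0, t_start, times, y, c, kappa, sigma, p0,
    u, u_res, dt, guided, ess_frac, sort_before_resample,
):
    """Scalar-state bootstrap / guided-MDB particle filter; returns the
    log-likelihood estimate (or -inf on weight collapse)."""
    N = u.shape[0]
    L = times.shape[0]
    X = np.full(N, x0)
    logW = np.full(N, -math.log(N))
    s2 = sigma * sigma
    ll = 0.0
    t_prev = t_start
    for l in range(L):
        lw = np.zeros(N)
        gap = times[l] - t_prev
        if gap > 0.0:
            n_sub = int(math.ceil(gap / dt - 1e-9))
            if n_sub < 1:
                n_sub = 1
            dts = gap / n_sub
            for s in range(n_sub):
                ts = t_prev + s * dts
                a, G = moments(X, c, kappa, ts)
                if guided:
                    delta = times[l] - ts
                    for n in range(N):
                        g = G[n] + 1e-12
                        psi = p0 * p0 * g * delta + s2
                        K = g * p0 / psi
                        resid = y[l] - p0 * (X[n] + a[n] * delta)
                        mu = X[n] + (a[n] + K * resid) * dts
                        var = (g - K * p0 * g * dts) * dts + 1e-12
                        z = u[n, l, s, 0]
                        xn = mu + math.sqrt(var) * z
                        gd = g * dts + 1e-12
                        diff = xn - X[n] - a[n] * dts
                        lw[n] += -0.5 * (math.log(gd) + diff * diff / gd)
                        lw[n] += 0.5 * (math.log(var) + z * z)
                        X[n] = xn
                else:
                    for n in range(N):
                        X[n] = X[n] + a[n] * dts + math.sqrt(G[n] * dts) * u[n, l, s, 0]
        # observation weight and loglik increment
        mx = -np.inf
        for n in range(N):
            resid = y[l] - p0 * X[n]
            lw[n] += logW[n] - 0.5 * (_LOG2PI + math.log(s2) + resid * resid / s2)
            if lw[n] > mx:
                mx = lw[n]
        if mx == -np.inf or not math.isfinite(mx):
            return -np.inf
        acc = 0.0
        for n in range(N):
            acc += math.exp(lw[n] - mx)
        incr = mx + math.log(acc)
        ll += incr
        for n in range(N):
            logW[n] = lw[n] - incr
        if l < L - 1:
            ess_inv = 0.0
            for n in range(N):
                w = math.exp(logW[n])
                ess_inv += w * w
            if 1.0 / ess_inv < ess_frac * N:
                W = np.empty(N)
                tot = 0.0
                for n in range(N):
                    W[n] = math.exp(logW[n])
                    tot += W[n]
                W /= tot
                if sort_before_resample:
                    order = np.argsort(X)
                    X = X[order]
                    W = W[order]
                u01 = 0.5 * (1.0 + math.erf(u_res[l] / _SQRT2))
                idx = _systematic(W, u01)
                X = X[idx]
                for n in range(N):
                    logW[n] = -math.log(N)
        t_prev = times[l]
    return ll
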