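"""Compiled bootstrap particle filter for jump dynamics (SSA / Extrande).

Used when the model provides a compiled propensity hook and the observation
is a scalar linear function of the state with additive Gaussian noise.
Jump filters always consume fresh randomness (auxiliary-number correlation
is not feasible when the number of event draws varies), so the kernel seeds
numba's RNG once per call.  The weight arithmetic mirrors
:mod:`ssmem.filters`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._pf_d1 import _systematic

_LOG2PI = math.log(2.0 * math.pi)


@njit(nogil=True, fastmath=True)
def pf_jump_kernel(
    stoich, prop_into, extrande, n_grid, safety, x0, t_start, times, y, c,
    kappa, sigma, pvec, N, ess_frac, seed, max_events,
):
    np.random.seed(seed)
    d = stoich.shape[0]
    R = stoich.shape[1]
    L = times.shape[0]
    X = np.empty((N, d))
    for n in range(N):
        for k in range(d):
            X[n, k] = x0[k]
    logW = np.full(N, -math.log(N))
    s2 = sigma * sigma
    ll = 0.0
    t_prev = t_start
    f = np.ones(R)  # per-reaction time-profile inflation factors
    for l in range(L):
        t1 = times[l]
        if t1 > t_prev:
            if extrande:
                # Per-reaction max/min ratio of the propensity over a time
                # grid at the entry state.  For propensities factorising as
                # (time profile) x (state part) this ratio is state-free, so
                # B = safety * sum_j f_j h_j(x, t_now) dominates the total
                # propensity over the remaining window from any state; every
                # candidate still checks the bound, so a non-factorising
                # model fails loudly rather than silently.
                hmax = np.zeros(R)
                hmin = np.full(R, np.inf)
                hbuf = np.empty(R)
                for k in range(n_grid):
                    tg = t_prev + (t1 - t_prev) * k / (n_grid - 1)
                    prop_into(hbuf, X[0], c, kappa, tg)
                    h = hbuf
                    for j in range(R):
                        if h[j] > hmax[j]:
                            hmax[j] = h[j]
                        if h[j] < hmin[j]:
                            hmin[j] = h[j]
                fmax = 1.0
                for j in range(R):
                    if hmin[j] > 0.0:
                        f[j] = hmax[j] / hmin[j]
                        if f[j] > fmax:
                            fmax = f[j]
                    else:
                        f[j] = -1.0  # undetermined at this state
                for j in range(R):
                    if f[j] < 0.0:
                        f[j] = fmax
            h = np.empty(R)
            for n in range(N):
                x = X[n].copy()
                t = t_prev
                ev = 0
                prop_into(h, x, c, kappa, t)
                while True:
                    B = 0.0
                    if extrande:
                        for j in range(R):
                            B += f[j] * h[j]
                        B *= safety
                    else:
                        for j in range(R):
                            B += h[j]
                    if B <= 0.0:
                        break
                    t = t + (-math.log(np.random.random())) / B
                    if t >= t1:
                        break
                    prop_into(h, x, c, kappa, t)
                    a0 = 0.0
                    for j in range(R):
                        a0 += h[j]
                    if extrande and a0 > B:
                        return np.nan  # bound violated; caller raises
                    u = np.random.random() * B
                    if u <= a0:
                        acc = 0.0
                        jf = -1
                        for j in range(R):
                            acc += h[j]
                            if u <= acc:
                                jf = j
                                break
                        if jf >= 0:
                            for k in range(d):
                                x[k] += stoich[k, jf]
                            prop_into(h, x, c, kappa, t)
                            ev += 1
                            if ev > max_events:
                                return np.nan
                X[n] = x
        mx = -np.inf
        lw = np.empty(N)
        for n in range(N):
            g = 0.0
            for k in range(d):
                g += pvec[k] * X[n, k]
            resid = y[l] - g
            lw[n] = logW[n] - 0.5 * (_LOG2PI + math.log(s2) + resid * resid / s2)
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
                idx = _systematic(W, np.random.random())
                X = X[idx].copy()
                for n in range(N):
                    logW[n] = -math.log(N)
        t_prev = t1
    return ll
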