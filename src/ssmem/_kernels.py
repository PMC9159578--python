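"""Inner event loops for the exact jump-process simulators.

Each kernel is written once as a plain function and compiled with numba;
the uncompiled original is kept as a fallback for models whose propensity
hook is a plain Python callable.  Kernels advance a block of particles over
one inter-observation interval and report a status code instead of raising
(numba-compatible error handling):

    0 ok, 1 event cap exceeded, 2 Extrande bound violated (deficit reported),
    3 invalid (negative / non-finite) propensity.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_EVENT_CAP = 1
STATUS_BOUND_VIOLATION = 2
STATUS_BAD_PROPENSITY = 3


def ssa_propagate(stoich, prop, c, kappa, X, t0, t1, max_events, seed):
    """Gillespie direct method: advance each row of X from t0 to t1 in place."""
    np.random.seed(seed)
    N, d = X.shape
    R = stoich.shape[1]
    for n in range(N):
        x = X[n].copy()
        t = t0
        ev = 0
        while True:
            h = prop(x, c, kappa, t)
            a0 = 0.0
            for j in range(R):
                hj = h[j]
                if not np.isfinite(hj) or hj < 0.0:
                    return STATUS_BAD_PROPENSITY, t, 0.0
                a0 += hj
            if a0 <= 0.0:
                break
            t = t + (-np.log(np.random.random())) / a0
            if t >= t1:
                break
            u = np.random.random() * a0
            acc = 0.0
            jf = R - 1
            for j in range(R):
                acc += h[j]
                if u <= acc:
                    jf = j
                    break
            for k in range(d):
                x[k] += stoich[k, jf]
            ev += 1
            if ev > max_events:
                return STATUS_EVENT_CAP, t, 0.0
        X[n] = x
    return STATUS_OK, t1, 0.0


def extrande_propagate(
    stoich, prop, c, kappa, X, t0, t1, n_grid, safety, bound_const, max_events, seed
):
    """Extrande thinning: exact simulation with time-varying propensities.

    A candidate event stream fires at rate B >= sup total propensity on the
    lookahead window (here the whole interval [t0, t1]); reaction j fires
    with probability h_j/B, otherwise the candidate is virtual.  When
    ``bound_const > 0`` it is used as B directly.  Otherwise B =
    safety * sum_j f_j h_j(x, t_now), where f_j is the max/min ratio of
    propensity j over an ``n_grid`` time grid at the interval's entry state:
    for propensities factorising into (time profile) x (state part) this
    ratio is state-free, so the bound stays valid as the state evolves.
    Every candidate checks the bound; a violation (e.g. a non-factorising
    propensity outrunning the safety factor) is status 2 with the deficit.
    """
    np.random.seed(seed)
    N, d = X.shape
    R = stoich.shape[1]
    cand_cap = 100 * max_events
    f = np.ones(R)
    if bound_const <= 0.0:
        hmax = np.zeros(R)
        hmin = np.full(R, np.inf)
        for k in range(n_grid):
            tg = t0 + (t1 - t0) * k / (n_grid - 1)
            h = prop(X[0], c, kappa, tg)
            for j in range(R):
                hj = h[j]
                if not np.isfinite(hj) or hj < 0.0:
                    return STATUS_BAD_PROPENSITY, tg, 0.0
                if hj > hmax[j]:
                    hmax[j] = hj
                if hj < hmin[j]:
                    hmin[j] = hj
        fmax = 1.0
        for j in range(R):
            if hmin[j] > 0.0:
                f[j] = hmax[j] / hmin[j]
                if f[j] > fmax:
                    fmax = f[j]
            else:
                f[j] = -1.0
        for j in range(R):
            if f[j] < 0.0:
                f[j] = fmax
    for n in range(N):
        x = X[n].copy()
        t = t0
        ev = 0
        cand = 0
        h = prop(x, c, kappa, t)
        while True:
            if bound_const > 0.0:
                B = bound_const
            else:
                B = 0.0
                for j in range(R):
                    B += f[j] * h[j]
                B *= safety
            if B <= 0.0:
                break
            t = t + (-np.log(np.random.random())) / B
            if t >= t1:
                break
            cand += 1
            if cand > cand_cap:
                return STATUS_EVENT_CAP, t, 0.0
            h = prop(x, c, kappa, t)
            a0 = 0.0
            for j in range(R):
                hj = h[j]
                if not np.isfinite(hj) or hj < 0.0:
                    return STATUS_BAD_PROPENSITY, t, 0.0
                a0 += hj
            if a0 > B:
                return STATUS_BOUND_VIOLATION, t, a0 - B
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
                    h = prop(x, c, kappa, t)
                    ev += 1
                    if ev > max_events:
                        return STATUS_EVENT_CAP, t, 0.0
        X[n] = x
    return STATUS_OK, t1, 0.0


ssa_propagate_jit = njit(ssa_propagate, nogil=True, fastmath=True)
extrande_propagate_jit = njit(extrande_propagate, nogil=True, fastmath=True)
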