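"""Particle filters: unbiased estimation of the per-cell likelihood
pi(y^(i) | c^(i), kappa, xi) by sequential Monte Carlo.

Two filters are provided: a bootstrap filter (particles propagated blindly
with the model simulator, weighted by the observation density) and a guided
filter using the modified diffusion bridge (MDB) proposal, which steers
Langevin particles toward the next observation and is markedly more
efficient for models with stochastic events.

Correlated pseudo-marginal support: for the tau-leap and Langevin
integrators every random draw a filter run consumes comes from a fixed
pre-allocated array of standard normals (the "auxiliary numbers" u).
Between MCMC iterations u is refreshed by the autoregressive kernel
u' = rho u + sqrt(1 - rho^2) zeta, which preserves the N(0,1) marginal and
correlates successive likelihood estimates.  SSA/Extrande consume fresh
randomness (event counts vary), so they require rho = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy.special import logsumexp, ndtr

from .network import SSMEMModel, ReactionNetwork, observation_logdensity
from .simulate import (
    ExtrandeBound,
    drift_and_cov,
    extrande_propagate_block,
    langevin_substep,
    n_noise,
    ssa_propagate_block,
    tauleap_substep,
    _substep_grid,
)

__all__ = [
    "PFConfig",
    "AuxiliaryNumbers",
    "LogLikEstimate",
    "make_auxiliary",
    "refresh_auxiliary",
    "systematic_resample",
    "pf_loglik",
    "pf_loglik_guided_mdb",
]

_JUMP_INTEGRATORS = ("ssa", "extrande")
_APPROX_INTEGRATORS = ("tauleap", "langevin")


@dataclass
class PFConfig:
    """Particle filter configuration.

    rho is the auxiliary-number refresh correlation in [0, 1); rho > 0 is
    only feasible for the tau-leap and Langevin integrators.  The guided
    MDB filter requires the Langevin integrator and a linear-Gaussian
    observation model.
    """

    n_particles: int = 50
    kind: str = "bootstrap"
    integrator: str = "langevin"
    dt: float = 0.1
    rho: float = 0.0
    resample: str = "systematic"
    ess_threshold: float = 0.5
    extrande_bound: Optional[ExtrandeBound] = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.kind not in ("bootstrap", "guided_mdb"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.integrator not in _JUMP_INTEGRATORS + _APPROX_INTEGRATORS:
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.rho > 0.0 and self.integrator not in _APPROX_INTEGRATORS:
            raise ValueError("correlated auxiliary numbers (rho > 0) require the tau-leap or Langevin integrator")
        if self.kind == "guided_mdb" and self.integrator != "langevin":
            raise ValueError("the guided MDB filter requires the Langevin integrator")
        if not (0.0 < self.ess_threshold <= 1.0):
            raise ValueError("ess_threshold must lie in (0, 1]")


@dataclass
class AuxiliaryNumbers:
    """Fixed-layout standard normals driving one filter run.

    normals: (N, n_intervals, max_substeps, n_draw); resamp: (n_intervals,)
    normals whose Phi-transform supplies the systematic-resampling uniforms,
    so resampling too is correlated across iterations.
    """

    normals: np.ndarray
    resamp: np.ndarray

    def copy(self) -> "AuxiliaryNumbers":
        return AuxiliaryNumbers(self.normals.copy(), self.resamp.copy())


@dataclass
class LogLikEstimate:
    """log of the unbiased likelihood estimate, with per-time increments and
    filter diagnostics (ESS trace, resample count)."""

    value: float
    increments: np.ndarray
    ess_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_resamples: int = 0


def _interval_layout(times: np.ndarray, dt: float, t_start: float):
    times = np.asarray(times, dtype=float)
    edges = np.concatenate([[t_start], times])
    n_sub = [
        max(1, int(np.ceil((b - a) / dt - 1e-9))) if b > a else 0
        for a, b in zip(edges[:-1], edges[1:])
    ]
    return n_sub


def make_auxiliary(
    model: SSMEMModel,
    times: np.ndarray,
    cfg: PFConfig,
    rng: Union[int, np.random.Generator],
    t_start: float = 0.0,
) -> AuxiliaryNumbers:
    """Allocate the auxiliary-number block for one (model, data, config)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    L = len(np.asarray(times))
    if cfg.integrator in _JUMP_INTEGRATORS:
        return AuxiliaryNumbers(np.empty((cfg.n_particles, L, 0, 0)), rng.standard_normal(L))
    n_draw = max(n_noise(model.dynamics), _dim(model))
    max_sub = max(_interval_layout(times, cfg.dt, t_start) + [1])
    normals = rng.standard_normal((cfg.n_particles, L, max_sub, n_draw))
    return AuxiliaryNumbers(normals, rng.standard_normal(L))


def _dim(model: SSMEMModel) -> int:
    return model.dynamics.n_species


def refresh_auxiliary(
    u: AuxiliaryNumbers, rho: float, rng: np.random.Generator
) -> AuxiliaryNumbers:
    """Autoregressive refresh u' = rho u + sqrt(1 - rho^2) zeta; rho = 0
    gives an independent block, and the N(0,1) marginal is preserved for
    any rho in [0, 1)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    s = np.sqrt(1.0 - rho * rho)
    return AuxiliaryNumbers(
        rho * u.normals + s * rng.standard_normal(u.normals.shape),
        rho * u.resamp + s * rng.standard_normal(u.resamp.shape),
    )


def systematic_resample(weights: np.ndarray, u_resample: float) -> np.ndarray:
    """Systematic resampling: offspring counts have expectation N * weights.

    ``u_resample`` is a single uniform on [0, 1) shared by the N strata.
    """
    weights = np.asarray(weights, dtype=float)
    N = weights.shape[0]
    positions = (u_resample + np.arange(N)) / N
    cum = np.cumsum(weights)
    cum[-1] = 1.0  # guard rounding
    return np.searchsorted(cum, positions, side="right").clip(0, N - 1)


def _sorted_order(X: np.ndarray) -> np.ndarray:
    # Euclidean order on state: first coordinate, then lexicographic
    keys = tuple(X[:, k] for k in reversed(range(X.shape[1])))
    return np.lexsort(keys)


class _Weights:
    """Normalised log-weight bookkeeping shared by both filters."""

    def __init__(self, N: int):
        self.N = N
        self.logW = np.full(N, -np.log(N))
        self.increments: List[float] = []
        self.ess_trace: List[float] = []
        self.n_resamples = 0

    def absorb(self, lw: np.ndarray) -> float:
        """Fold per-particle log-weight terms; return the loglik increment."""
        tot = self.logW + lw
        incr = logsumexp(tot)
        if not np.isfinite(incr):
            return -np.inf
        self.logW = tot - incr
        return float(incr)

    def ess(self) -> float:
        return float(1.0 / np.exp(logsumexp(2.0 * self.logW)))

    def maybe_resample(self, X, cfg: PFConfig, u_res: float, is_last: bool):
        ess = self.ess()
        self.ess_trace.append(ess)
        if is_last or ess >= cfg.ess_threshold * self.N:
            return X
        W = np.exp(self.logW)
        W /= W.sum()
        if cfg.rho > 0.0:
            order = _sorted_order(X)
            X, W = X[order], W[order]
        idx = systematic_resample(W, u_res)
        self.n_resamples += 1
        self.logW = np.full(self.N, -np.log(self.N))
        return X[idx]


def _propagate_bootstrap(model, cfg, X, c, kappa, t0, t1, u_block, rng):
    dyn = model.dynamics
    if cfg.integrator == "ssa":
        ssa_propagate_block(dyn, X, c, kappa, t0, t1, rng)
        return X
    if cfg.integrator == "extrande":
        extrande_propagate_block(dyn, X, c, kappa, t0, t1, rng, cfg.extrande_bound)
        return X
    steps, starts = _substep_grid(t0, t1, cfg.dt)
    if cfg.integrator == "tauleap":
        R = dyn.n_reactions
        for s, (h_dt, ts) in enumerate(zip(steps, starts)):
            X = tauleap_substep(dyn, X, c, kappa, ts, h_dt, z=u_block[:, s, :R])
        return X
    nz = n_noise(dyn)
    for s, (h_dt, ts) in enumerate(zip(steps, starts)):
        X = langevin_substep(dyn, X, c, kappa, ts, h_dt, u_block[:, s, :nz])
    return X


def pf_loglik(
    model: SSMEMModel,
    times: np.ndarray,
    y: np.ndarray,
    c: np.ndarray,
    kappa: np.ndarray,
    xi: np.ndarray,
    u: AuxiliaryNumbers,
    cfg: PFConfig,
    rng: Optional[np.random.Generator] = None,
    t_start: float = 0.0,
) -> LogLikEstimate:
    """Bootstrap particle filter estimate of log pi(y | c, kappa, xi).

    exp(value) is unbiased for the true likelihood.  A proposal under which
    all particle weights vanish at some observation yields value = -inf
    (a signal for Metropolis rejection, never an exception).
    """
    if cfg.kind == "guided_mdb":
        return pf_loglik_guided_mdb(model, times, y, c, kappa, xi, u, cfg, rng, t_start)
    if _fast_d1_applicable(model, cfg):
        return _pf_d1_dispatch(model, times, y, c, kappa, xi, u, cfg, t_start, guided=False)
    times = np.asarray(times, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float).reshape(len(times), -1))
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    if cfg.integrator in _JUMP_INTEGRATORS and rng is None:
        raise ValueError("SSA/Extrande filters need an rng (fresh randomness each call)")
    if _fast_jump_applicable(model, cfg):
        return _pf_jump_dispatch(model, times, y, c, kappa, xi, cfg, rng, t_start)
    N = cfg.n_particles
    X = np.tile(model.initial_state(c), (N, 1))
    wts = _Weights(N)
    increments = np.zeros(len(times))
    u_res = ndtr(u.resamp) if u.resamp.size else np.full(len(times), 0.5)
    t_prev = t_start
    for l, t in enumerate(times):
        if t > t_prev:
            X = _propagate_bootstrap(model, cfg, X, c, kappa, t_prev, t, u.normals[:, l], rng)
        lobs = observation_logdensity(model.obs, y[l], X, t, xi)
        lobs = np.atleast_1d(lobs).astype(float)
        if cfg.integrator == "tauleap":
            lobs = np.where(np.any(X < 0, axis=-1), -np.inf, lobs)
        incr = wts.absorb(lobs)
        increments[l] = incr
        if incr == -np.inf:
            return LogLikEstimate(-np.inf, increments, np.asarray(wts.ess_trace), wts.n_resamples)
        X = wts.maybe_resample(X, cfg, u_res[l], is_last=(l == len(times) - 1))
        t_prev = t
    return LogLikEstimate(
        float(np.sum(increments)), increments, np.asarray(wts.ess_trace), wts.n_resamples
    )


def _fast_jump_applicable(model: SSMEMModel, cfg: PFConfig) -> bool:
    dyn = model.dynamics
    P = model.obs.linear_P
    b = cfg.extrande_bound
    return (
        cfg.integrator in _JUMP_INTEGRATORS
        and isinstance(dyn, ReactionNetwork)
        and dyn.propensity_jit is not None
        and P is not None
        and P.shape[0] == 1
        and (b is None or (b.bound_fn is None and b.constant is None))
    )


def _make_prop_into(prop_jit):
    from numba import njit

    @njit(nogil=True)
    def prop_into(h, x, c, kappa, t):
        hh = prop_jit(x, c, kappa, t)
        for j in range(hh.shape[0]):
            h[j] = hh[j]

    return prop_into


def _pf_jump_dispatch(model, times, y, c, kappa, xi, cfg, rng, t_start):
    from ._pf_jump import pf_jump_kernel
    from .simulate import SimulationError

    dyn = model.dynamics
    if dyn.propensity_jit_into is None:
        # cached on the network so the kernel specialises once per model
        dyn.propensity_jit_into = _make_prop_into(dyn.propensity_jit)
    bound = cfg.extrande_bound or ExtrandeBound()
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sigma = float(np.atleast_1d(np.asarray(xi, float))[0])
    value = pf_jump_kernel(
        dyn.stoich.astype(np.float64), dyn.propensity_jit_into,
        cfg.integrator == "extrande", bound.n_grid, bound.safety,
        np.asarray(model.initial_state(np.asarray(c, float)), float),
        float(t_start), times, y, np.asarray(c, float), np.asarray(kappa, float),
        sigma, model.obs.linear_P[0].astype(np.float64), cfg.n_particles,
        cfg.ess_threshold, int(rng.integers(0, 2**31 - 1)), 1_000_000,
    )
    if np.isnan(value):
        raise SimulationError("jump-filter propagation failed (bound violation or event cap)")
    return LogLikEstimate(float(value), np.empty(0))


def _fast_d1_applicable(model: SSMEMModel, cfg: PFConfig) -> bool:
    dyn = model.dynamics
    P = model.obs.linear_P
    return (
        cfg.integrator == "langevin"
        and getattr(dyn, "langevin_moments_jit", None) is not None
        and dyn.n_species == 1
        and P is not None
        and P.shape == (1, 1)
    )


def _pf_d1_dispatch(model, times, y, c, kappa, xi, u, cfg, t_start, guided):
    from ._pf_d1 import pf_d1_kernel

    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sigma = float(np.atleast_1d(np.asarray(xi, float))[0])
    x0 = float(np.atleast_1d(model.initial_state(np.asarray(c, float)))[0])
    value = pf_d1_kernel(
        model.dynamics.langevin_moments_jit, x0, float(t_start), times, y,
        np.asarray(c, float), np.asarray(kappa, float), sigma,
        float(model.obs.linear_P[0, 0]), u.normals, u.resamp, cfg.dt,
        guided, cfg.ess_threshold, cfg.rho > 0.0,
    )
    return LogLikEstimate(float(value), np.empty(0))


def _gauss_logpdf_batch(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(x; mean, cov) for batched (N, d) points and (N, d, d) covariances."""
    d = x.shape[-1]
    L = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(L, diff[..., None])[..., 0]
    maha = np.sum(sol**2, axis=-1)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def pf_loglik_guided_mdb(
    model: SSMEMModel,
    times: np.ndarray,
    y: np.ndarray,
    c: np.ndarray,
    kappa: np.ndarray,
    xi: np.ndarray,
    u: AuxiliaryNumbers,
    cfg: PFConfig,
    rng: Optional[np.random.Generator] = None,
    t_start: float = 0.0,
) -> LogLikEstimate:
    """Guided particle filter with the modified diffusion bridge proposal.

    Valid for Langevin dynamics observed as y = P x + eps with Gaussian eps.
    With Delta the time remaining to the next observation, a = a(x) the
    drift and Gamma = Gamma(x) the diffusion covariance, each Euler sub-step
    of length dt proposes from

        psi   = P Gamma P' Delta + Sigma_eps
        mu    = x + [a + Gamma P' psi^{-1} (y - P(x + a Delta))] dt
        Sigma = (Gamma - Gamma P' psi^{-1} P Gamma dt) dt

    (the one-step-conditioned Gaussian under the locally linear
    approximation).  Importance weights accumulate the log-ratio of the
    blind Euler transition density to this proposal density, keeping the
    likelihood estimator unbiased; as sigma -> infinity the proposal decays
    to the unconditioned Euler step and the weights to bootstrap weights.
    """
    if cfg.integrator != "langevin":
        raise ValueError("the guided MDB filter requires the Langevin integrator")
    P = model.obs.linear_P
    if P is None or model.obs.error != "gaussian_additive":
        raise ValueError(
            "guided filtering needs an observation model with linear structure "
            "y = P x + eps and additive Gaussian noise"
        )
    if _fast_d1_applicable(model, cfg):
        return _pf_d1_dispatch(model, times, y, c, kappa, xi, u, cfg, t_start, guided=True)
    times = np.asarray(times, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float).reshape(len(times), -1))
    sigma = np.atleast_1d(np.asarray(xi, dtype=float))
    sig_eps = np.diag(sigma**2)
    N = cfg.n_particles
    d = _dim(model)
    X = np.tile(model.initial_state(c), (N, 1))
    wts = _Weights(N)
    increments = np.zeros(len(times))
    u_res = ndtr(u.resamp)
    jitter = 1e-12 * np.eye(d)
    t_prev = t_start
    for l, t in enumerate(times):
        lw_path = np.zeros(N)
        if t > t_prev:
            steps, starts = _substep_grid(t_prev, t, cfg.dt)
            for s, (dt_s, ts) in enumerate(zip(steps, starts)):
                delta = t - ts
                a, G = drift_and_cov(model.dynamics, X, c, kappa, ts)
                G = G + jitter
                GPt = G @ P.T  # (N, d, q)
                psi = P @ G @ P.T * delta + sig_eps  # (N, q, q)
                K = GPt @ np.linalg.inv(psi)  # (N, d, q)
                resid = y[l] - (X + a * delta) @ P.T  # (N, q)
                mu = X + (a + (K @ resid[..., None])[..., 0]) * dt_s
                cov = (G - (K @ np.swapaxes(GPt, -1, -2)) * dt_s) * dt_s
                cov = cov + jitter
                z = u.normals[:, l, s, :d]
                Lc = np.linalg.cholesky(cov)
                X_new = mu + (Lc @ z[..., None])[..., 0]
                lw_path += _gauss_logpdf_batch(X_new, X + a * dt_s, G * dt_s + jitter)
                lw_path -= _gauss_logpdf_batch(X_new, mu, cov)
                X = X_new
        lobs = np.atleast_1d(observation_logdensity(model.obs, y[l], X, t, xi)).astype(float)
        incr = wts.absorb(lw_path + lobs)
        increments[l] = incr
        if incr == -np.inf:
            return LogLikEstimate(-np.inf, increments, np.asarray(wts.ess_trace), wts.n_resamples)
        X = wts.maybe_resample(X, cfg, u_res[l], is_last=(l == len(times) - 1))
        t_prev = t
    return LogLikEstimate(
        float(np.sum(increments)), increments, np.asarray(wts.ess_trace), wts.n_resamples
    )
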