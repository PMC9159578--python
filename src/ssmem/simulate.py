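"""Forward simulation of the latent Markov process.

Four integrators are provided, mirroring the usual hierarchy for chemical
kinetics:

* :func:`simulate_ssa` — Gillespie direct method, exact for time-invariant
  propensities;
* :func:`simulate_extrande` — Extrande thinning, exact for time-varying
  propensities (e.g. a circadian-modulated transcription rate);
* :func:`simulate_tauleap` — fixed-step Poisson tau-leaping, valid when
  propensities change little within a step (leap condition 1);
* :func:`simulate_langevin` — Euler-Maruyama on the chemical Langevin
  equation, additionally requiring large propensities (leap condition 2).

The engine never switches integrators automatically: tau-leap/Langevin are
used only where the model declares the leap conditions acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from . import _kernels
from .network import Dynamics, ReactionNetwork, SDEDynamics

try:  # numba dispatcher type, used to select the compiled path
    from numba.core.dispatcher import Dispatcher
except ImportError:  # pragma: no cover
    Dispatcher = ()

__all__ = [
    "Trajectory",
    "ExtrandeBound",
    "SimulationError",
    "simulate_ssa",
    "simulate_extrande",
    "simulate_tauleap",
    "simulate_langevin",
]


class SimulationError(RuntimeError):
    """Raised when a simulator detects an invalid model or runaway dynamics."""


@dataclass
class Trajectory:
    """Recorded sample path: ``states[l]`` is the state at ``times[l]``."""

    times: np.ndarray
    states: np.ndarray


@dataclass
class ExtrandeBound:
    """Upper bound policy for Extrande thinning.

    Either a user ``bound_fn(x, c, kappa, t_lo, t_hi) -> B`` guaranteed to
    dominate the total propensity on the window, or a constant, or (default)
    a numeric bound: max total propensity on an ``n_grid`` time grid at the
    current state, times ``safety``.  A violation detected at an event time
    is an error reporting the time and deficit.
    """

    bound_fn: Optional[Callable] = None
    constant: Optional[float] = None
    n_grid: int = 6
    safety: float = 1.5


def _as_generator(rng: Union[int, np.random.Generator]) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _select_ssa_kernel(network: ReactionNetwork):
    if network.propensity_jit is not None:
        return _kernels.ssa_propagate_jit, network.propensity_jit
    return _kernels.ssa_propagate, network.propensity


def _select_extrande_kernel(network: ReactionNetwork):
    if network.propensity_jit is not None:
        return _kernels.extrande_propagate_jit, network.propensity_jit
    return _kernels.extrande_propagate, network.propensity


def _raise_for_status(status: int, t: float, deficit: float, name: str) -> None:
    if status == _kernels.STATUS_OK:
        return
    if status == _kernels.STATUS_EVENT_CAP:
        raise SimulationError(f"{name}: event count cap exceeded near t={t:.6g} (runaway network?)")
    if status == _kernels.STATUS_BOUND_VIOLATION:
        raise SimulationError(
            f"{name}: Extrande bound violated at t={t:.6g} (total propensity exceeds bound by {deficit:.6g})"
        )
    raise SimulationError(f"{name}: negative or non-finite propensity at t={t:.6g}")


def ssa_propagate_block(
    network: ReactionNetwork,
    X: np.ndarray,
    c: np.ndarray,
    kappa: np.ndarray,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    max_events: int = 1_000_000,
) -> None:
    """Advance an (N, d) particle block with the SSA in place (one interval)."""
    kern, prop = _select_ssa_kernel(network)
    status, t, deficit = kern(
        network.stoich.astype(np.float64), prop, np.asarray(c, float),
        np.asarray(kappa, float), X, float(t0), float(t1), max_events,
        _kernel_seed(rng),
    )
    _raise_for_status(status, t, deficit, "ssa")


def extrande_propagate_block(
    network: ReactionNetwork,
    X: np.ndarray,
    c: np.ndarray,
    kappa: np.ndarray,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    bound: Optional[ExtrandeBound] = None,
    max_events: int = 1_000_000,
) -> None:
    """Advance an (N, d) particle block with Extrande in place (one interval)."""
    bound = bound or ExtrandeBound()
    if bound.bound_fn is not None:
        # user bound: python path, bound fixed for the interval per particle
        for n in range(X.shape[0]):
            B = float(bound.bound_fn(X[n], c, kappa, t0, t1))
            status, t, deficit = _kernels.extrande_propagate(
                network.stoich.astype(np.float64), network.propensity,
                np.asarray(c, float), np.asarray(kappa, float), X[n : n + 1],
                float(t0), float(t1), bound.n_grid, bound.safety, B,
                max_events, _kernel_seed(rng),
            )
            _raise_for_status(status, t, deficit, "extrande")
        return
    kern, prop = _select_extrande_kernel(network)
    const = -1.0 if bound.constant is None else float(bound.constant)
    status, t, deficit = kern(
        network.stoich.astype(np.float64), prop, np.asarray(c, float),
        np.asarray(kappa, float), X, float(t0), float(t1),
        bound.n_grid, bound.safety, const, max_events, _kernel_seed(rng),
    )
    _raise_for_status(status, t, deficit, "extrande")


def _record_jump_path(propagate, x0, out_times, t_start) -> Trajectory:
    out_times = np.asarray(out_times, dtype=float)
    x = np.array(x0, dtype=float, copy=True).reshape(1, -1)
    states = np.empty((out_times.shape[0], x.shape[1]))
    t_prev = t_start
    for l, t in enumerate(out_times):
        if t > t_prev:
            propagate(x, t_prev, t)
        states[l] = x[0]
        t_prev = t
    return Trajectory(times=out_times, states=states)


def simulate_ssa(
    network: ReactionNetwork,
    c: np.ndarray,
    kappa: np.ndarray,
    x0: np.ndarray,
    out_times: np.ndarray,
    rng: Union[int, np.random.Generator],
    t_start: float = 0.0,
    max_events: int = 1_000_000,
) -> Trajectory:
    """Exact draw from the master equation, recorded at ``out_times`` by
    last-event hold (state is piecewise constant between firings)."""
    rng = _as_generator(rng)
    return _record_jump_path(
        lambda X, a, b: ssa_propagate_block(network, X, c, kappa, a, b, rng, max_events),
        x0, out_times, t_start,
    )


def simulate_extrande(
    network: ReactionNetwork,
    c: np.ndarray,
    kappa: np.ndarray,
    x0: np.ndarray,
    out_times: np.ndarray,
    rng: Union[int, np.random.Generator],
    bound: Optional[ExtrandeBound] = None,
    t_start: float = 0.0,
    max_events: int = 1_000_000,
) -> Trajectory:
    """Exact simulation with time-varying propensities by thinning."""
    rng = _as_generator(rng)
    return _record_jump_path(
        lambda X, a, b: extrande_propagate_block(network, X, c, kappa, a, b, rng, bound, max_events),
        x0, out_times, t_start,
    )


# ---------------------------------------------------------------------------
# approximate integrators (vectorised over a leading particle axis)
# ---------------------------------------------------------------------------


def n_noise(dynamics: Dynamics) -> int:
    """Number of driving noises per sub-step: one per reaction for a
    network's Langevin/tau-leap update, one per component for a plain SDE."""
    if isinstance(dynamics, ReactionNetwork):
        return dynamics.n_reactions
    return dynamics.n_species


def _propensities_clipped(network: ReactionNetwork, X, c, kappa, t) -> np.ndarray:
    # negative excursions feed zero into the propensity (reflecting clamp)
    h = np.asarray(network.propensity(np.maximum(X, 0.0), c, kappa, t), dtype=float)
    return np.maximum(h, 0.0)


def tauleap_substep(
    network: ReactionNetwork, X, c, kappa, t, dt, rng=None, z=None
) -> np.ndarray:
    """One Poisson leap x <- x + S K, K_j ~ Poisson(h_j dt).

    Either ``rng`` draws the Poisson counts directly, or ``z`` supplies
    standard normals converted through the Poisson inverse CDF of their
    Phi-transform (the fixed auxiliary-number layout used by the correlated
    particle filter).
    """
    h = _propensities_clipped(network, X, c, kappa, t)
    lam = h * dt
    if z is not None:
        from scipy.special import ndtr
        from scipy.stats import poisson

        K = poisson.ppf(np.clip(ndtr(z), 1e-15, 1.0 - 1e-15), lam)
        K = np.where(lam > 0, K, 0.0)
    else:
        K = rng.poisson(lam)
    return X + K @ network.stoich.T.astype(float)


def langevin_substep(dynamics: Dynamics, X, c, kappa, t, dt, z) -> np.ndarray:
    """One Euler-Maruyama step of the chemical Langevin equation,
    x <- x + S h dt + S diag(h)^(1/2) sqrt(dt) z  (network form), or
    x <- x + a dt + s sqrt(dt) z (direct SDE form).  ``z`` is (N, n_noise)."""
    if isinstance(dynamics, ReactionNetwork):
        h = _propensities_clipped(dynamics, X, c, kappa, t)
        S = dynamics.stoich.astype(float)
        return X + (h * dt + np.sqrt(h * dt) * z) @ S.T
    a = np.asarray(dynamics.drift(X, c, kappa, t), dtype=float)
    s = np.asarray(dynamics.diffusion(X, c, kappa, t), dtype=float)
    return X + a * dt + s * np.sqrt(dt) * z


def drift_and_cov(dynamics: Dynamics, X, c, kappa, t):
    """Drift a(x) and diffusion covariance Gamma(x) of the Langevin form,
    shapes (N, d) and (N, d, d); used by the guided bridge filter."""
    if isinstance(dynamics, ReactionNetwork):
        h = _propensities_clipped(dynamics, X, c, kappa, t)
        S = dynamics.stoich.astype(float)
        a = h @ S.T
        G = np.einsum("nr,dr,er->nde", h, S, S)
        return a, G
    a = np.asarray(dynamics.drift(X, c, kappa, t), dtype=float)
    s = np.asarray(dynamics.diffusion(X, c, kappa, t), dtype=float)
    d = X.shape[-1]
    G = np.zeros((X.shape[0], d, d))
    idx = np.arange(d)
    G[:, idx, idx] = s**2
    return a, G


def _substep_grid(t0: float, t1: float, dt: float):
    n_sub = max(1, int(np.ceil((t1 - t0) / dt - 1e-9)))
    edges = np.linspace(t0, t1, n_sub + 1)
    return np.diff(edges), edges[:-1]


def simulate_tauleap(
    network: ReactionNetwork,
    c: np.ndarray,
    kappa: np.ndarray,
    x0: np.ndarray,
    out_times: np.ndarray,
    dt: float,
    rng: Union[int, np.random.Generator],
    t_start: float = 0.0,
) -> Trajectory:
    """Fixed-step tau-leaping; the last sub-step of each inter-output gap is
    truncated so recorded times are hit exactly.  Species driven negative are
    clamped to zero (the clamp also applies inside propensity evaluation)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = _as_generator(rng)
    out_times = np.asarray(out_times, dtype=float)
    x = np.array(x0, dtype=float, copy=True).reshape(1, -1)
    states = np.empty((out_times.shape[0], x.shape[1]))
    t_prev = t_start
    for l, t in enumerate(out_times):
        if t > t_prev:
            steps, starts = _substep_grid(t_prev, t, dt)
            for h_dt, ts in zip(steps, starts):
                x = tauleap_substep(network, x, c, kappa, ts, h_dt, rng=rng)
            x = np.maximum(x, 0.0)
        states[l] = x[0]
        t_prev = t
    return Trajectory(times=out_times, states=states)


def simulate_langevin(
    dynamics: Dynamics,
    c: np.ndarray,
    kappa: np.ndarray,
    x0: np.ndarray,
    out_times: np.ndarray,
    dt: float,
    rng: Union[int, np.random.Generator],
    t_start: float = 0.0,
) -> Trajectory:
    """Euler-Maruyama integration of the chemical Langevin SDE; states are
    real-valued and may go negative (propensity inputs are clamped at 0)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = _as_generator(rng)
    out_times = np.asarray(out_times, dtype=float)
    x = np.array(x0, dtype=float, copy=True).reshape(1, -1)
    nz = n_noise(dynamics)
    states = np.empty((out_times.shape[0], x.shape[1]))
    t_prev = t_start
    step_index = 0
    for l, t in enumerate(out_times):
        if t > t_prev:
            steps, starts = _substep_grid(t_prev, t, dt)
            for h_dt, ts in zip(steps, starts):
                z = rng.standard_normal((1, nz))
                x = langevin_substep(dynamics, x, c, kappa, ts, h_dt, z)
                step_index += 1
                if not np.all(np.isfinite(x)):
                    raise SimulationError(f"langevin: non-finite state at step {step_index}")
        states[l] = x[0]
        t_prev = t
    return Trajectory(times=out_times, states=states)
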