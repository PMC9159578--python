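"""Adaptive random-walk proposals for the pseudo-marginal Metropolis steps.

Three classical schemes are provided:

* ``AM`` — adaptive Metropolis: proposal covariance (2.38^2/p) * C_hat + eps I
  with C_hat the running empirical covariance of the chain;
* ``AM_global`` — AM with an additional global log-scale lambda adapted
  toward a target acceptance rate;
* ``RAM`` — robust adaptive Metropolis: a Cholesky factor S adapted by
  rank-one updates S S' = S (I + gamma_n (alpha_n - alpha*) z z'/|z|^2) S'
  so the realised acceptance rate is driven to alpha*.

All adaptation step sizes decay as gamma_n = n^(-beta), beta in (0.5, 1]
(diminishing adaptation).  Proposals operate on the unconstrained (log)
parameter scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["AdaptiveProposalState", "propose", "adapt"]

_AM_SCALE = 2.38


@dataclass
class AdaptiveProposalState:
    kind: str
    dim: int
    target_accept: float = 0.234
    beta: float = 0.66
    sigma0: float = 0.1
    eps_reg: float = 1e-8
    warmup: int = 10
    n: int = 0
    mean: np.ndarray = None
    cov: np.ndarray = None
    chol: np.ndarray = None  # RAM factor S
    lam: float = 0.0  # AM_global log-scale
    last_z: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("AM", "AM_global", "RAM"):
            raise ValueError(f"unknown proposal kind {self.kind!r}")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")
        if not (0.5 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0.5, 1]")
        if self.mean is None:
            self.mean = np.zeros(self.dim)
        if self.cov is None:
            self.cov = np.eye(self.dim)
        if self.chol is None:
            self.chol = self.sigma0 * np.eye(self.dim)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "dim": self.dim,
            "target_accept": self.target_accept,
            "beta": self.beta,
            "sigma0": self.sigma0,
            "eps_reg": self.eps_reg,
            "warmup": self.warmup,
            "n": self.n,
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "chol": self.chol.tolist(),
            "lam": self.lam,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdaptiveProposalState":
        d = dict(d)
        for key in ("mean", "cov", "chol"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def _safe_cholesky(mat: np.ndarray, eps: float) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        warnings.warn("proposal covariance not positive definite; jitter added")
        jitter = eps
        for _ in range(12):
            try:
                return np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
            except np.linalg.LinAlgError:
                jitter *= 10.0
        raise


def _proposal_factor(state: AdaptiveProposalState) -> np.ndarray:
    p = state.dim
    if state.kind == "RAM":
        return state.chol
    if state.n < state.warmup:
        base = state.sigma0 * np.eye(p)
    else:
        scaled = (_AM_SCALE**2 / p) * state.cov + state.eps_reg * np.eye(p)
        base = _safe_cholesky(scaled, state.eps_reg)
    if state.kind == "AM_global":
        return np.exp(state.lam) * base
    return base


def propose(
    state: AdaptiveProposalState, theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw theta' = theta + S z, z ~ N(0, I), with S the current factor.

    The noise vector z is stashed on the state (``last_z``) for the RAM
    rank-one update in :func:`adapt`.
    """
    theta = np.asarray(theta, dtype=float)
    z = rng.standard_normal(state.dim)
    state.last_z = z
    return theta + _proposal_factor(state) @ z


def adapt(
    state: AdaptiveProposalState,
    theta_current: np.ndarray,
    alpha: float,
    z: Optional[np.ndarray] = None,
) -> AdaptiveProposalState:
    """One adaptation step after an accept/reject decision.

    ``theta_current`` is the chain's current value (post-decision);
    ``alpha`` the acceptance probability of the move; ``z`` the proposal
    noise (defaults to the stashed draw).  AM tracks the running empirical
    mean/covariance; AM_global additionally nudges its global log-scale by
    gamma_n (alpha - alpha*); RAM applies its rank-one Cholesky update.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    theta_current = np.asarray(theta_current, dtype=float)
    state.n += 1
    n = state.n
    gamma = n ** (-state.beta)
    if state.kind in ("AM", "AM_global"):
        # exact running empirical moments (initial cov bias decays as 1/n)
        delta = theta_current - state.mean
        state.mean = state.mean + delta / n
        state.cov = state.cov + (np.outer(delta, theta_current - state.mean) - state.cov) / n
        if state.kind == "AM_global":
            state.lam += gamma * (alpha - state.target_accept)
    else:  # RAM
        z = state.last_z if z is None else np.asarray(z, dtype=float)
        if z is None or not np.any(z):
            return state
        u = z / np.linalg.norm(z)
        eta = min(1.0, state.dim * gamma)
        M = state.chol @ (
            np.eye(state.dim) + eta * (alpha - state.target_accept) * np.outer(u, u)
        ) @ state.chol.T
        state.chol = _safe_cholesky(M, state.eps_reg)
    return state
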