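"""Exact likelihood and gold-standard posterior for the Ornstein-Uhlenbeck
benchmark.

The OU process dX = theta1 (theta2 - X) dt + theta3 dW observed through
y = x + eps, eps ~ N(0, sigma^2), is linear-Gaussian, so its likelihood is
available in closed form through the Kalman filter.  Every stochastic
component of the engine (particle filters, pseudo-marginal Gibbs samplers)
is validated against this oracle: the filter for unbiasedness, the samplers
for posterior exactness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = ["OUModel", "kalman_loglik", "exact_gibbs_ou"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class OUModel:
    """Mean-reverting OU process with additive Gaussian observation error.

    theta1: mean-reversion rate (1/time), theta2: stationary mean,
    theta3: diffusion scale; sigma: observation error SD.  The exact
    discrete transition over a gap ``delta`` is
    ``N(theta2 + (x - theta2) e^{-theta1 delta},
    theta3^2 (1 - e^{-2 theta1 delta}) / (2 theta1))``.
    """

    theta1: float
    theta2: float
    theta3: float
    sigma: float

    def __post_init__(self) -> None:
        if self.theta1 <= 0 or self.theta3 <= 0 or self.sigma <= 0:
            raise ValueError("theta1, theta3 and sigma must be positive")

    @property
    def stationary_var(self) -> float:
        return self.theta3**2 / (2.0 * self.theta1)

    def transition(self, x: np.ndarray, delta: float) -> tuple[np.ndarray, float]:
        """Exact one-gap transition mean and variance."""
        a = np.exp(-self.theta1 * delta)
        mean = self.theta2 + (x - self.theta2) * a
        var = self.stationary_var * (1.0 - a * a)
        return mean, var

    def simulate(
        self,
        times: np.ndarray,
        rng: Union[int, np.random.Generator],
        x0: Optional[float] = None,
    ) -> np.ndarray:
        """Exact-path simulation at the given times (stationary init by default)."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        times = np.asarray(times, dtype=float)
        x = np.empty(times.shape[0])
        if x0 is None:
            x_prev = self.theta2 + np.sqrt(self.stationary_var) * rng.standard_normal()
            t_prev = 0.0
        else:
            x_prev, t_prev = float(x0), 0.0
        for l, t in enumerate(times):
            mean, var = self.transition(x_prev, t - t_prev)
            x[l] = mean + np.sqrt(var) * rng.standard_normal()
            x_prev, t_prev = x[l], t
        return x


def kalman_loglik(
    ou: OUModel,
    times: np.ndarray,
    y: np.ndarray,
    x0_law: str = "stationary",
    x0: float = 0.0,
) -> float:
    """Exact log-likelihood log pi(y | theta, sigma) via scalar Kalman recursions.

    ``x0_law`` is ``"stationary"`` (default: X(t) started from the stationary
    law at the first observation gap measured from t=0) or ``"fixed"`` with
    the given ``x0`` at time 0.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    r = ou.sigma**2
    if x0_law == "stationary":
        m, p = ou.theta2, ou.stationary_var
        t_prev = times[0]  # stationary law holds at any time
    elif x0_law == "fixed":
        m, p = float(x0), 0.0
        t_prev = 0.0
    else:
        raise ValueError("x0_law must be 'stationary' or 'fixed'")
    ll = 0.0
    for t, obs in zip(times, y):
        a = np.exp(-ou.theta1 * (t - t_prev))
        m = ou.theta2 + (m - ou.theta2) * a
        p = p * a * a + ou.stationary_var * (1.0 - a * a)
        s = p + r
        innov = obs - m
        ll += -0.5 * (_LOG2PI + np.log(s) + innov * innov / s)
        k = p / s
        m = m + k * innov
        p = p * (1.0 - k)
        t_prev = t
    return float(ll)


def kalman_loglik_euler(
    ou: OUModel, times: np.ndarray, y: np.ndarray, dt: float, x0: float
) -> float:
    """Exact likelihood of the *Euler-discretised* OU state-space model.

    The Euler path x_{k+1} = x_k + theta1 (theta2 - x_k) dt + theta3 sqrt(dt) z
    is itself linear-Gaussian, so the likelihood the Langevin particle
    filter unbiasedly estimates is computable in closed form: the matched
    oracle for filter-unbiasedness checks at finite dt.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    r = ou.sigma**2
    m, p = float(x0), 0.0
    t_prev = 0.0
    ll = 0.0
    for t, obs in zip(times, y):
        gap = t - t_prev
        n_sub = max(1, int(np.ceil(gap / dt - 1e-9)))
        dts = gap / n_sub
        a = 1.0 - ou.theta1 * dts
        q = ou.theta3**2 * dts
        for _ in range(n_sub):
            m = ou.theta2 + (m - ou.theta2) * a
            p = p * a * a + q
        s = p + r
        innov = obs - m
        ll += -0.5 * (_LOG2PI + np.log(s) + innov * innov / s)
        k = p / s
        m, p = m + k * innov, p * (1.0 - k)
        t_prev = t
    return float(ll)


def exact_gibbs_ou(data, priors, cfg, rng):
    """Gold-standard Gibbs run for the OU SSMEM: the same sampler loops as
    :func:`ssmem.gibbs.run_inference`, with every particle-filter likelihood
    estimate replaced by the exact Kalman likelihood (exact marginal MH).

    Parameters mirror ``run_inference``: ``data`` is a Dataset of OU cells,
    ``priors`` a :class:`ssmem.gibbs.Priors`, ``cfg`` an InferenceConfig
    (its PF settings are ignored).
    """
    from .benchmarks import make_ou_model
    from .gibbs import run_inference

    model = make_ou_model().model

    def loglik(times, y, c, kappa, xi):
        ou = OUModel(theta1=c[0], theta2=c[1], theta3=c[2], sigma=xi[0])
        # the benchmark starts each cell at its own stationary mean theta2
        return kalman_loglik(ou, times, y, x0_law="fixed", x0=c[1])

    return run_inference(model, data, cfg, rng, priors=priors, exact_loglik=loglik)
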