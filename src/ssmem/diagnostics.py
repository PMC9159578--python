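"""Evaluation toolbox: particle-count tuning, multivariate effective sample
size, first-order Wasserstein distances and posterior visual checks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import wasserstein_distance

from .filters import PFConfig, make_auxiliary, pf_loglik
from .network import SSMEMModel, sample_individual_parameters, PopulationLaw

__all__ = [
    "TuningResult",
    "QuantileBands",
    "tune_particles",
    "multi_ess",
    "wasserstein1",
    "wasserstein_exact_multivariate",
    "posterior_visual_check",
]


def _default_ladder(n_max: int = 500) -> List[int]:
    ladder, n = [], 10.0
    while round(n) <= n_max:
        ladder.append(int(round(n)))
        n *= 1.5
    return ladder


@dataclass
class TuningResult:
    """Chosen particle counts: per individual (perturbed mode) or one global
    count for the summed log-likelihood (unperturbed mode); the smallest
    ladder entry meeting the variance criterion."""

    n_particles: Union[int, List[int]]
    variance: Union[float, List[float]]
    replicates: int
    exhausted: bool = False


def tune_particles(
    model: SSMEMModel,
    data,
    theta_pilot,
    cfg: PFConfig,
    rng: Union[int, np.random.Generator],
    mode: str = "perturbed",
    n_replicates: int = 25,
    var_target: float = 2.0,
    ladder: Optional[Sequence[int]] = None,
) -> TuningResult:
    """Pick the particle count N at a pilot parameter point.

    ``theta_pilot`` is a tuple ``(c, kappa, xi)`` with ``c`` of shape
    (M, dim_c).  For each ladder N the log-likelihood estimator variance is
    measured over ``n_replicates`` independent filter runs; the chosen N is
    the smallest with variance <= ``var_target`` (default 2.0, the usual
    pseudo-marginal guidance).  Perturbed mode tunes each individual's own
    filter variance; unperturbed mode tunes the variance of the summed
    log-likelihood over all M individuals (which grows with M — the cost
    the perturbed sampler avoids).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    c_all, kappa, xi = theta_pilot
    c_all = np.atleast_2d(np.asarray(c_all, dtype=float))
    ladder = list(ladder) if ladder is not None else _default_ladder()
    M = data.M

    def loglik_matrix(N: int) -> np.ndarray:
        out = np.empty((n_replicates, M))
        cfg_n = PFConfig(**{**cfg.__dict__, "n_particles": N})
        for r in range(n_replicates):
            for i, ind in enumerate(data):
                u = make_auxiliary(model, ind.times, cfg_n, rng)
                out[r, i] = pf_loglik(
                    model, ind.times, ind.y, c_all[i], kappa, xi, u, cfg_n, rng=rng
                ).value
        return out

    if mode == "perturbed":
        chosen = [None] * M
        var_at = [np.inf] * M
        for N in ladder:
            ll = loglik_matrix(N)
            v = np.var(np.where(np.isfinite(ll), ll, np.nan), axis=0, ddof=1)
            v = np.where(np.all(np.isfinite(ll), axis=0), v, np.inf)
            for i in range(M):
                if chosen[i] is None and v[i] <= var_target:
                    chosen[i], var_at[i] = N, float(v[i])
            if all(ch is not None for ch in chosen):
                return TuningResult(chosen, var_at, n_replicates)
        for i in range(M):
            if chosen[i] is None:
                chosen[i], var_at[i] = ladder[-1], float("nan")
        return TuningResult(chosen, var_at, n_replicates, exhausted=True)
    # unperturbed: variance of the summed loglik, one global N
    for N in ladder:
        ll = loglik_matrix(N)
        total = ll.sum(axis=1)
        if np.all(np.isfinite(total)):
            v = float(np.var(total, ddof=1))
            if v <= var_target:
                return TuningResult(N, v, n_replicates)
    return TuningResult(ladder[-1], float("nan"), n_replicates, exhausted=True)


def multi_ess(samples: np.ndarray) -> float:
    """Multivariate effective sample size of an MCMC sample matrix (n, p):

        mESS = n * (det(Lambda) / det(Sigma))^(1/p)

    with Lambda the sample covariance and Sigma the multivariate
    batch-means estimate of the long-run (Markov-chain) covariance, using
    batch size floor(sqrt(n)).
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.ndim != 2:
        raise ValueError("samples must be a 2-d array (n, p)")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more draws than dimensions")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        k = int(np.argwhere(sd == 0)[0][0])
        raise ValueError(f"column {k} is constant; mESS undefined")
    lam = np.cov(X, rowvar=False).reshape(p, p)
    b = int(np.floor(np.sqrt(n)))
    a = n // b
    means = X[: a * b].reshape(a, b, p).mean(axis=1)
    grand = X[: a * b].mean(axis=0)
    dev = means - grand
    sigma = b * (dev.T @ dev) / (a - 1)
    sign_l, logdet_l = np.linalg.slogdet(lam)
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    if sign_l <= 0 or sign_s <= 0:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        k = int(np.unravel_index(np.argmax(np.abs(corr)), corr.shape)[1])
        raise ValueError(f"singular covariance (column {k} is degenerate/duplicated)")
    return float(n * np.exp((logdet_l - logdet_s) / p))


def wasserstein1(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """First-order 1-d Wasserstein distance between two sample sets
    (mean absolute difference of matched order statistics for equal sizes,
    quantile-function integral otherwise)."""
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    return float(wasserstein_distance(a, b))


def wasserstein_exact_multivariate(a: np.ndarray, b: np.ndarray) -> float:
    """Exact small-n first-order Wasserstein distance between equal-size
    multivariate sample sets, by optimal assignment on Euclidean costs."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.ndim == 2 and a.shape[0] != b.shape[0]:
        raise ValueError("equal sample sizes required for the exact solver")
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    ri, ci = linear_sum_assignment(cost)
    return float(cost[ri, ci].mean())


@dataclass
class QuantileBands:
    """95% credibility envelopes of population quantile curves.

    For each requested quantile q, ``lower[q]`` and ``upper[q]`` bound the
    simulated population's q-quantile at every time point, across posterior
    repeats.
    """

    times: np.ndarray
    quantiles: Sequence[float]
    lower: Dict[float, np.ndarray]
    upper: Dict[float, np.ndarray]
    median: Dict[float, np.ndarray]
    n_dropped: int = 0

    def covers(self, observed_quantiles: Dict[float, np.ndarray]) -> float:
        """Fraction of (quantile, time) points of observed quantile curves
        falling inside the bands."""
        hits = total = 0
        for q in self.quantiles:
            obs = np.asarray(observed_quantiles[q], dtype=float)
            hits += int(np.sum((obs >= self.lower[q]) & (obs <= self.upper[q])))
            total += obs.size
        return hits / total


def plot_quantile_bands(bands: "QuantileBands", observed=None, ax=None):
    """Render quantile-band envelopes (and optionally observed quantile
    curves) in the usual overlay style.  Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for q in bands.quantiles:
        ax.fill_between(bands.times, bands.lower[q], bands.upper[q], alpha=0.3,
                        label=f"q={q} 95% band")
        if observed is not None:
            ax.plot(bands.times, observed[q], lw=1.5)
    ax.set_xlabel("time")
    ax.set_ylabel("observable")
    ax.legend(fontsize="small")
    return ax


def posterior_visual_check(
    simulate_cell: Callable,
    samples,
    times: np.ndarray,
    M_cells: int = 40,
    n_repeats: int = 500,
    rng: Union[int, np.random.Generator] = 0,
    quantiles: Sequence[float] = (0.05, 0.5, 0.95),
) -> QuantileBands:
    """Posterior-predictive quantile-band check.

    Each repeat draws one saved posterior sample (eta, kappa, xi), simulates
    ``M_cells`` complete cells (population draw -> exact simulator ->
    observation noise) via ``simulate_cell(c, kappa, xi, times, rng) -> y``,
    computes the population quantiles per time point, and the bands are the
    95% intervals of each quantile across repeats.  Failed repeats are
    dropped and counted.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    times = np.asarray(times, dtype=float)
    if samples.n_save == 0:
        raise ValueError("empty posterior sample")
    curves = {q: [] for q in quantiles}
    dropped = 0
    for _ in range(n_repeats):
        j = int(rng.integers(samples.n_save))
        pop = PopulationLaw(samples.mu[j], samples.omega[j])
        kappa, xi = samples.kappa[j], samples.xi[j]
        try:
            C = sample_individual_parameters(pop, M_cells, rng)
            Y = np.stack([
                np.asarray(simulate_cell(C[m], kappa, xi, times, rng), dtype=float).ravel()
                for m in range(M_cells)
            ])
        except Exception:
            dropped += 1
            continue
        for q in quantiles:
            curves[q].append(np.quantile(Y, q, axis=0))
    if not curves[quantiles[0]]:
        raise RuntimeError("every posterior-predictive repeat failed")
    lower, upper, median = {}, {}, {}
    for q in quantiles:
        arr = np.stack(curves[q])
        lower[q] = np.quantile(arr, 0.025, axis=0)
        upper[q] = np.quantile(arr, 0.975, axis=0)
        median[q] = np.quantile(arr, 0.5, axis=0)
    return QuantileBands(times, tuple(quantiles), lower, upper, median, dropped)
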