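"""The full inference engines: a three-step Metropolis-within-Gibbs sampler
and its scalable "perturbed" variant.

The target is the hierarchical posterior

    pi(c, kappa, eta, xi | y) ∝ pi(c, kappa, eta, xi) prod_i pi(y^(i) | c^(i), kappa, xi)

sampled by looping over

    1. per-individual blocks  pi(c^(i) | ...) — pseudo-marginal MH with a
       particle-filter likelihood estimate and correlated auxiliary numbers;
    2. the cell-constant block  pi(kappa, xi | ...) — pseudo-marginal MH on
       the product over all M individuals (unperturbed mode only);
    3. the population block  pi(eta | c) — a tractable conjugate
       Normal-Inverse-Wishart draw or an HMC step.

The perturbed variant lets the cell-constant parameters vary weakly between
cells, kappa^(i) ~ N(kappa_pop, delta^2 I) on the transformed scale (and
likewise xi).  The per-cell copies are then updated inside step 1 and the
population locations get closed-form Gaussian updates inside step 3, so the
expensive step 2 — whose summed log-likelihood estimate has variance growing
with M — disappears.  This is the default mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Union

import numpy as np
from scipy import stats

from .data import Dataset
from .filters import AuxiliaryNumbers, PFConfig, make_auxiliary, pf_loglik, refresh_auxiliary
from .network import NIWPrior, SSMEMModel, from_unconstrained, to_unconstrained
from .proposals import AdaptiveProposalState, adapt, propose

__all__ = [
    "Priors",
    "InferenceConfig",
    "ChainState",
    "PosteriorSamples",
    "run_inference",
    "sample_eta_conjugate",
    "EtaHMC",
    "step1_update_individuals",
    "step2_update_constants",
    "step3_update_population",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Priors:
    """Priors on the transformed (log) scale: a Normal-Inverse-Wishart
    hyperprior on (mu, Omega) and independent Gaussians on log kappa / log xi
    (log-normal priors on the natural scale)."""

    niw: NIWPrior
    kappa_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    kappa_sd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    xi_mean: np.ndarray = field(default_factory=lambda: np.zeros(1))
    xi_sd: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self) -> None:
        for name in ("kappa_mean", "kappa_sd", "xi_mean", "xi_sd"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))


@dataclass
class InferenceConfig:
    n_iterations: int = 1000
    burn_in: float = 0.2
    thinning: int = 1
    mode: str = "perturbed"
    delta: float = 0.1
    pf: PFConfig = field(default_factory=PFConfig)
    eta_kind: str = "conjugate_niw"
    proposal_kind: str = "RAM"
    target_accept: float = 0.234
    proposal_beta: float = 0.66
    sigma0: float = 0.1
    hmc_leapfrog: int = 10
    hmc_target: float = 0.8
    adapt_freeze: Optional[int] = None  # iteration after which adaptation stops

    def __post_init__(self) -> None:
        if self.mode not in ("perturbed", "unperturbed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.mode == "perturbed" and self.delta <= 0:
            raise ValueError("delta must be positive in perturbed mode")
        if self.eta_kind not in ("conjugate_niw", "hmc"):
            raise ValueError(f"unknown eta_kind {self.eta_kind!r}")


# ---------------------------------------------------------------------------
# chain state
# ---------------------------------------------------------------------------


@dataclass
class ChainState:
    """Everything the sampler carries between iterations.

    The pseudo-marginal bookkeeping invariant: ``logliks[i]`` is always the
    estimate produced with (``theta[i]``, cell constants, ``u[i]``).
    """

    theta: np.ndarray  # (M, p_block) transformed per-individual block
    kappa_t: np.ndarray  # transformed cell-constant kappa (pop location in perturbed mode)
    xi_t: np.ndarray
    mu: np.ndarray
    omega: np.ndarray
    logliks: np.ndarray
    u: List[Optional[AuxiliaryNumbers]]
    prop_ind: List[AdaptiveProposalState]
    prop_kx: Optional[AdaptiveProposalState]
    ind_rngs: List[np.random.Generator]
    global_rng: np.random.Generator
    iteration: int = 0
    accept_ind: np.ndarray = None
    accept_kx: int = 0
    eta_hmc: Optional["EtaHMC"] = None


@dataclass
class PosteriorSamples:
    """Saved posterior draws (post burn-in, thinned) plus acceptance summaries."""

    c: np.ndarray  # (n_save, M, dim_c), natural scale
    kappa: np.ndarray  # (n_save, dim_kappa), natural scale (population location)
    xi: np.ndarray  # (n_save, dim_xi)
    mu: np.ndarray  # (n_save, p)
    omega: np.ndarray  # (n_save, p, p)
    accept_rates: dict = field(default_factory=dict)

    @property
    def tau(self) -> np.ndarray:
        return np.sqrt(np.diagonal(self.omega, axis1=1, axis2=2))

    @property
    def n_save(self) -> int:
        return self.c.shape[0]


# ---------------------------------------------------------------------------
# eta step: conjugate NIW and HMC
# ---------------------------------------------------------------------------


def niw_posterior(prior: NIWPrior, V: np.ndarray) -> NIWPrior:
    """Analytic NIW update given rows v_i = log c^(i)."""
    V = np.atleast_2d(V)
    M = V.shape[0]
    if M == 0:
        return prior
    vbar = V.mean(axis=0)
    S = (V - vbar).T @ (V - vbar)
    lam_n = prior.lambda0 + M
    nu_n = prior.nu0 + M
    mu_n = (prior.lambda0 * prior.mu0 + M * vbar) / lam_n
    dev = (vbar - prior.mu0)[:, None]
    psi_n = prior.psi0 + S + (prior.lambda0 * M / lam_n) * (dev @ dev.T)
    return NIWPrior(mu0=mu_n, lambda0=lam_n, psi0=psi_n, nu0=nu_n)


def sample_eta_conjugate(
    prior: NIWPrior, V: np.ndarray, rng: np.random.Generator, family: str = "lognormal_full"
):
    """Exact draw (mu, Omega) from the NIW full conditional given log c rows.

    For the diagonal family each coordinate gets an independent scalar NIW
    update (off-diagonal covariance constrained to zero).
    """
    p = prior.mu0.shape[0]
    if family == "lognormal_diag" and p > 1:
        mu = np.empty(p)
        omega = np.zeros((p, p))
        for k in range(p):
            sub = NIWPrior(prior.mu0[k : k + 1], prior.lambda0,
                           prior.psi0[k : k + 1, k : k + 1], prior.nu0 - (p - 1))
            m, om = sample_eta_conjugate(sub, np.atleast_2d(V)[:, k : k + 1], rng)
            mu[k], omega[k, k] = m[0], om[0, 0]
        return mu, omega
    post = niw_posterior(prior, V)
    omega = stats.invwishart.rvs(df=post.nu0, scale=post.psi0, random_state=rng)
    omega = np.atleast_2d(omega)
    mu = rng.multivariate_normal(post.mu0, omega / post.lambda0, method="cholesky")
    return mu, omega


class EtaHMC:
    """Leapfrog HMC on eta = (mu, Omega) for non-conjugate use, parameterised
    by mu, the log-diagonal and (full family) strict lower triangle of the
    Cholesky factor of Omega.  Step size is tuned by dual averaging toward
    a target acceptance; the NIW prior density (plus the Cholesky transform
    Jacobian) is the default prior.
    """

    def __init__(self, prior: NIWPrior, family: str = "lognormal_full",
                 n_leapfrog: int = 10, target: float = 0.8, adapt_iters: int = 10**9):
        self.prior = prior
        self.family = family
        self.n_leapfrog = n_leapfrog
        self.target = target
        self.adapt_iters = adapt_iters
        self.p = prior.mu0.shape[0]
        self.log_eps = np.log(0.1)
        self._da_hbar = 0.0
        self._da_logeps_bar = self.log_eps
        self._da_mu = np.log(10.0) + self.log_eps
        self._da_t = 0
        self.n_divergent = 0

    # -- parameter packing ------------------------------------------------
    def _pack(self, mu, omega):
        p = self.p
        L = np.linalg.cholesky(omega)
        parts = [mu, np.log(np.diag(L))]
        if self.family == "lognormal_full" and p > 1:
            parts.append(L[np.tril_indices(p, -1)])
        return np.concatenate(parts)

    def _unpack(self, phi):
        p = self.p
        mu = phi[:p]
        L = np.zeros((p, p))
        L[np.diag_indices(p)] = np.exp(phi[p : 2 * p])
        if self.family == "lognormal_full" and p > 1:
            L[np.tril_indices(p, -1)] = phi[2 * p :]
        return mu, L

    # -- target ------------------------------------------------------------
    def _logp_grad(self, phi, V):
        p, pr = self.p, self.prior
        M = V.shape[0]
        mu, L = self._unpack(phi)
        omega = L @ L.T
        omega_inv = np.linalg.inv(omega)
        dev = V - mu
        S = dev.T @ dev
        dmu0 = (mu - pr.mu0)[:, None]
        C = pr.psi0 + pr.lambda0 * (dmu0 @ dmu0.T) + S
        alpha = -(pr.nu0 + p + 1 + 1 + M) / 2.0
        jac_coef = p - np.arange(p) + 1.0  # (p - j + 2) with 1-based j
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logp = alpha * logdet - 0.5 * np.trace(C @ omega_inv) + np.sum(jac_coef * np.log(np.diag(L)))
        # gradients
        g_mu = omega_inv @ dev.sum(axis=0) - pr.lambda0 * (omega_inv @ (mu - pr.mu0))
        G = alpha * omega_inv + 0.5 * omega_inv @ C @ omega_inv
        dL = 2.0 * (G @ L)
        g_logdiag = np.diag(dL) * np.diag(L) + jac_coef
        parts = [g_mu, g_logdiag]
        if self.family == "lognormal_full" and p > 1:
            parts.append(dL[np.tril_indices(p, -1)])
        return logp, np.concatenate(parts)

    # -- one HMC transition -------------------------------------------------
    def sample(self, V, mu, omega, rng: np.random.Generator):
        phi = self._pack(mu, omega)
        eps = float(np.exp(self.log_eps))
        logp0, grad = self._logp_grad(phi, V)
        mom = rng.standard_normal(phi.shape[0])
        H0 = logp0 - 0.5 * mom @ mom
        q, g = phi.copy(), grad
        m = mom + 0.5 * eps * g
        diverged = False
        for step in range(self.n_leapfrog):
            q = q + eps * m
            logp, g = self._logp_grad(q, V)
            if not np.isfinite(logp):
                diverged = True
                break
            m = m + (eps if step < self.n_leapfrog - 1 else 0.5 * eps) * g
        if diverged:
            alpha = 0.0
            self.n_divergent += 1
        else:
            H1 = logp - 0.5 * m @ m
            delta_h = H1 - H0
            if delta_h < -1000.0:  # divergence threshold on the energy error
                alpha = 0.0
                self.n_divergent += 1
            else:
                alpha = min(1.0, float(np.exp(min(delta_h, 0.0))))
        if alpha > 0 and rng.random() < alpha:
            phi = q
        # dual averaging of the step size
        if self._da_t < self.adapt_iters:
            self._da_t += 1
            t = self._da_t
            w = 1.0 / (t + 10.0)
            self._da_hbar = (1.0 - w) * self._da_hbar + w * (self.target - alpha)
            self.log_eps = self._da_mu - np.sqrt(t) / 0.05 * self._da_hbar
            eta = t ** (-0.75)
            self._da_logeps_bar = eta * self.log_eps + (1.0 - eta) * self._da_logeps_bar
        else:
            self.log_eps = self._da_logeps_bar
        mu_new, L = self._unpack(phi)
        return mu_new, L @ L.T


# ---------------------------------------------------------------------------
# block helpers
# ---------------------------------------------------------------------------


def _blocks(model: SSMEMModel, mode: str):
    part = model.partition
    if mode == "perturbed":
        return part.dim_c, part.dim_kappa, part.dim_xi
    return part.dim_c, 0, 0


def _split_theta(theta_i, model, mode):
    pc, pk, px = _blocks(model, mode)
    return theta_i[:pc], theta_i[pc : pc + pk], theta_i[pc + pk :]


def _natural(model: SSMEMModel, v, k_t, x_t):
    part = model.partition
    c = from_unconstrained(v, part.transform_c)
    kappa = from_unconstrained(k_t, part.transform_kappa)
    xi = from_unconstrained(x_t, part.transform_xi)
    return c, kappa, xi


def _gauss_logpdf(x, mean, sd):
    x, mean, sd = (np.atleast_1d(np.asarray(a, float)) for a in (x, mean, sd))
    if x.size == 0:
        return 0.0
    return float(np.sum(stats.norm.logpdf(x, mean, sd)))


def _mvn_logpdf(v, mu, omega):
    try:
        return float(stats.multivariate_normal.logpdf(v, mean=mu, cov=omega))
    except np.linalg.LinAlgError:
        return -np.inf


class _Engine:
    """Internal: binds model, data, config, priors and the likelihood backend."""

    def __init__(self, model, data, cfg, priors, exact_loglik):
        self.model, self.data, self.cfg, self.priors = model, data, cfg, priors
        self.exact = exact_loglik

    def loglik(self, i, c, kappa, xi, u, rng):
        ind = self.data[i]
        if self.exact is not None:
            return float(self.exact(ind.times, ind.y, c, kappa, xi))
        est = pf_loglik(self.model, ind.times, ind.y.ravel() if ind.y.shape[1] == 1 else ind.y,
                        c, kappa, xi, u, self.cfg.pf, rng=rng)
        return est.value

    def fresh_u(self, i, rng):
        if self.exact is not None:
            return None
        return make_auxiliary(self.model, self.data[i].times, self.cfg.pf, rng)

    def refreshed_u(self, u, rng):
        if self.exact is not None:
            return None
        return refresh_auxiliary(u, self.cfg.pf.rho, rng)


# ---------------------------------------------------------------------------
# Gibbs steps
# ---------------------------------------------------------------------------


def step1_update_individuals(state: ChainState, eng: _Engine) -> None:
    """Per-individual pseudo-marginal MH update of c^(i) (jointly with the
    per-cell kappa^(i), xi^(i) copies in perturbed mode)."""
    model, cfg, priors = eng.model, eng.cfg, eng.priors
    perturbed = cfg.mode == "perturbed"
    adapting = cfg.adapt_freeze is None or state.iteration < cfg.adapt_freeze
    for i in range(len(eng.data.individuals)):
        rng = state.ind_rngs[i]
        theta = state.theta[i]
        prop = state.prop_ind[i]
        theta_new = propose(prop, theta, rng)
        v, k_t, x_t = _split_theta(theta, model, cfg.mode)
        v2, k2_t, x2_t = _split_theta(theta_new, model, cfg.mode)
        if not perturbed:
            k_t = k2_t = state.kappa_t
            x_t = x2_t = state.xi_t
        c2, kappa2, xi2 = _natural(model, v2, k2_t, x2_t)
        u_new = eng.refreshed_u(state.u[i], rng)
        ll_new = eng.loglik(i, c2, kappa2, xi2, u_new, rng)
        lp_new = _mvn_logpdf(v2, state.mu, state.omega) + ll_new
        lp_old = _mvn_logpdf(v, state.mu, state.omega) + state.logliks[i]
        if perturbed:
            lp_new += _gauss_logpdf(k2_t, state.kappa_t, cfg.delta)
            lp_new += _gauss_logpdf(x2_t, state.xi_t, cfg.delta)
            lp_old += _gauss_logpdf(k_t, state.kappa_t, cfg.delta)
            lp_old += _gauss_logpdf(x_t, state.xi_t, cfg.delta)
        if np.isfinite(lp_new):
            alpha = min(1.0, float(np.exp(min(lp_new - lp_old, 0.0))))
        else:
            alpha = 0.0
        if alpha > 0.0 and rng.random() < alpha:
            state.theta[i] = theta_new
            state.logliks[i] = ll_new
            state.u[i] = u_new
            state.accept_ind[i] += 1
        if adapting:
            adapt(prop, state.theta[i], alpha)


def step2_update_constants(state: ChainState, eng: _Engine) -> None:
    """Joint pseudo-marginal MH update of the cell-constant block (kappa, xi)
    on the product likelihood over all individuals (unperturbed mode only).
    All M likelihoods are re-estimated with refreshed correlated auxiliary
    numbers; on acceptance every stored estimate and u block is replaced."""
    model, cfg, priors = eng.model, eng.cfg, eng.priors
    rng = state.global_rng
    pk = model.partition.dim_kappa
    theta = np.concatenate([state.kappa_t, state.xi_t])
    prop = state.prop_kx
    theta_new = propose(prop, theta, rng)
    k2_t, x2_t = theta_new[:pk], theta_new[pk:]
    M = len(eng.data.individuals)
    u_new: List[Optional[AuxiliaryNumbers]] = []
    ll_new = np.zeros(M)
    ok = True
    for i in range(M):
        v = _split_theta(state.theta[i], model, cfg.mode)[0]
        c_i, kappa2, xi2 = _natural(model, v, k2_t, x2_t)
        u_i = eng.refreshed_u(state.u[i], state.ind_rngs[i])
        u_new.append(u_i)
        ll_new[i] = eng.loglik(i, c_i, kappa2, xi2, u_i, state.ind_rngs[i])
        if ll_new[i] == -np.inf:
            ok = False
            break
    prior_new = _gauss_logpdf(k2_t, eng.priors.kappa_mean, eng.priors.kappa_sd) + \
        _gauss_logpdf(x2_t, eng.priors.xi_mean, eng.priors.xi_sd)
    prior_old = _gauss_logpdf(state.kappa_t, eng.priors.kappa_mean, eng.priors.kappa_sd) + \
        _gauss_logpdf(state.xi_t, eng.priors.xi_mean, eng.priors.xi_sd)
    if ok:
        lp_new = prior_new + float(np.sum(ll_new))
        lp_old = prior_old + float(np.sum(state.logliks))
        alpha = min(1.0, float(np.exp(min(lp_new - lp_old, 0.0)))) if np.isfinite(lp_new) else 0.0
    else:
        alpha = 0.0
    if alpha > 0.0 and rng.random() < alpha:
        state.kappa_t, state.xi_t = k2_t, x2_t
        state.logliks = ll_new
        state.u = u_new
        state.accept_kx += 1
    adapting = eng.cfg.adapt_freeze is None or state.iteration < eng.cfg.adapt_freeze
    if adapting:
        adapt(prop, np.concatenate([state.kappa_t, state.xi_t]), alpha)


def step3_update_population(state: ChainState, eng: _Engine) -> None:
    """Tractable population update: (mu, Omega) from its NIW full
    conditional (or one HMC transition), plus — in perturbed mode — the
    Gaussian full-conditional draws of the kappa/xi population locations."""
    model, cfg, priors = eng.model, eng.cfg, eng.priors
    rng = state.global_rng
    pc = model.partition.dim_c
    V = state.theta[:, :pc]
    if cfg.eta_kind == "conjugate_niw":
        state.mu, state.omega = sample_eta_conjugate(
            priors.niw, V, rng, family=model.population.family
        )
    else:
        state.mu, state.omega = state.eta_hmc.sample(V, state.mu, state.omega, rng)
    if cfg.mode == "perturbed":
        M = state.theta.shape[0]
        pk = model.partition.dim_kappa
        kx_i = state.theta[:, pc:]
        for block, mean0, sd0, lo in (
            ("kappa", priors.kappa_mean, priors.kappa_sd, 0),
            ("xi", priors.xi_mean, priors.xi_sd, pk),
        ):
            dim = len(mean0)
            if dim == 0:
                continue
            vals = kx_i[:, lo : lo + dim]
            prec = M / cfg.delta**2 + 1.0 / sd0**2
            mean_post = (vals.sum(axis=0) / cfg.delta**2 + mean0 / sd0**2) / prec
            draw = mean_post + rng.standard_normal(dim) / np.sqrt(prec)
            if block == "kappa":
                state.kappa_t = draw
            else:
                state.xi_t = draw


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _init_state(model, data, cfg, priors, eng, rng) -> ChainState:
    master = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    M = data.M
    children = master.spawn(M + 1)
    ind_rngs, global_rng = children[:M], children[M]
    p = model.partition.dim_c
    pr = priors.niw
    mu0 = pr.mu0.copy()
    denom = pr.nu0 - p - 1
    omega0 = pr.psi0 / denom if denom > 0 else pr.psi0 / pr.nu0
    if model.population.family == "lognormal_diag":
        omega0 = np.diag(np.diag(omega0))
    kappa_t = priors.kappa_mean.copy()
    xi_t = priors.xi_mean.copy()
    pc, pk, px = _blocks(model, cfg.mode)
    theta = np.empty((M, pc + pk + px))
    logliks = np.full(M, -np.inf)
    u: List[Optional[AuxiliaryNumbers]] = [None] * M
    chol0 = np.linalg.cholesky(omega0 + 1e-12 * np.eye(p))
    for i in range(M):
        r = ind_rngs[i]
        for attempt in range(100):
            v = mu0 + chol0 @ r.standard_normal(p)
            theta[i, :pc] = v
            if pk + px:
                theta[i, pc : pc + pk] = kappa_t
                theta[i, pc + pk :] = xi_t
            c_i, kap, xi = _natural(model, v, kappa_t, xi_t)
            u[i] = eng.fresh_u(i, r)
            logliks[i] = eng.loglik(i, c_i, kap, xi, u[i], r)
            if np.isfinite(logliks[i]):
                break
        else:
            raise RuntimeError(f"could not initialise individual {i}: likelihood estimate is -inf")
    mk_prop = lambda dim: AdaptiveProposalState(
        kind=cfg.proposal_kind, dim=dim, target_accept=cfg.target_accept,
        beta=cfg.proposal_beta, sigma0=cfg.sigma0,
    )
    prop_ind = [mk_prop(pc + pk + px) for _ in range(M)]
    prop_kx = None
    if cfg.mode == "unperturbed":
        dim_kx = model.partition.dim_kappa + model.partition.dim_xi
        prop_kx = mk_prop(dim_kx) if dim_kx else None
    eta_hmc = None
    if cfg.eta_kind == "hmc":
        eta_hmc = EtaHMC(priors.niw, family=model.population.family,
                         n_leapfrog=cfg.hmc_leapfrog, target=cfg.hmc_target)
    return ChainState(
        theta=theta, kappa_t=kappa_t, xi_t=xi_t, mu=mu0, omega=omega0,
        logliks=logliks, u=u, prop_ind=prop_ind, prop_kx=prop_kx,
        ind_rngs=list(ind_rngs), global_rng=global_rng,
        accept_ind=np.zeros(M), eta_hmc=eta_hmc,
    )


def run_inference(
    model: SSMEMModel,
    data: Dataset,
    cfg: InferenceConfig,
    rng: Union[int, np.random.Generator],
    priors: Priors,
    exact_loglik: Optional[Callable] = None,
    resume: Optional[ChainState] = None,
    n_iterations: Optional[int] = None,
):
    """Run the Gibbs sampler; returns (PosteriorSamples, final ChainState).

    ``exact_loglik(times, y, c, kappa, xi)`` replaces the particle-filter
    estimate when given (exact marginal MH — the Kalman gold-standard path).
    Passing ``resume=state`` continues a previous run bit-identically.
    """
    eng = _Engine(model, data, cfg, priors, exact_loglik)
    state = resume if resume is not None else _init_state(model, data, cfg, priors, eng, rng)
    n_iter = cfg.n_iterations if n_iterations is None else n_iterations
    start = state.iteration
    burn = int(np.floor(cfg.burn_in * (start + n_iter)))
    saved_c, saved_kappa, saved_xi, saved_mu, saved_omega = [], [], [], [], []
    part = model.partition
    pc = part.dim_c
    for it in range(start, start + n_iter):
        step1_update_individuals(state, eng)
        if cfg.mode == "unperturbed" and state.prop_kx is not None:
            step2_update_constants(state, eng)
        step3_update_population(state, eng)
        state.iteration = it + 1
        if it >= burn and (it - burn) % cfg.thinning == 0:
            saved_c.append(from_unconstrained(state.theta[:, :pc].copy(), part.transform_c))
            saved_kappa.append(from_unconstrained(state.kappa_t.copy(), part.transform_kappa))
            saved_xi.append(from_unconstrained(state.xi_t.copy(), part.transform_xi))
            saved_mu.append(state.mu.copy())
            saved_omega.append(state.omega.copy())
    total = state.iteration
    samples = PosteriorSamples(
        c=np.asarray(saved_c), kappa=np.asarray(saved_kappa), xi=np.asarray(saved_xi),
        mu=np.asarray(saved_mu), omega=np.asarray(saved_omega),
        accept_rates={
            "individual": (state.accept_ind / max(total, 1)).tolist(),
            "cell_constant": state.accept_kx / max(total, 1),
        },
    )
    return samples, state
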