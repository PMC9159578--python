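"""Synthetic benchmark systems and dataset generators.

Three systems exercise every part of the engine:

* ``circadian`` — a two-species gene-expression network (mRNA, protein;
  transcription, mRNA decay, translation, protein decay) whose
  transcription rate is modulated by a 24 h sine (the circadian clock).
  Time-varying propensities require the Extrande simulator; molecule
  numbers are kept low so intrinsic noise is strong.
* ``schlogl`` — the bistable Schlogl network (2X <-> 3X, 0 <-> X), where
  intrinsic noise makes cells stochastically migrate between a low and a
  high expression state.  Data are generated with the exact SSA; inference
  uses the Langevin integrator with the guided bridge filter.
* ``ou`` — the Ornstein-Uhlenbeck SDE, the linear-Gaussian system whose
  exact likelihood (Kalman filter) validates the stochastic machinery.

Every dataset is generated by the *exact* simulator for its system
(Extrande / SSA / exact OU transition), never by the approximate integrator
later used in inference.  True parameter values are package defaults chosen
to reproduce the qualitative regimes (low copy numbers, bistability,
well-conditioned recovery); each factory exposes them for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
from numba import njit

from .data import Dataset, Individual
from .filters import PFConfig
from .gibbs import Priors
from .kalman import OUModel
from .network import (
    NIWPrior,
    ObservationModel,
    ParameterPartition,
    PopulationLaw,
    ReactionNetwork,
    SDEDynamics,
    SSMEMModel,
)
from .simulate import simulate_extrande, simulate_ssa

__all__ = ["Benchmark", "BenchmarkSpec", "make_circadian_model", "make_schlogl_model",
           "make_ou_model", "generate_dataset", "get_benchmark"]


@dataclass
class BenchmarkSpec:
    """Fully-deterministic recipe for one synthetic dataset."""

    name: str
    M: int
    seed: int
    times: Optional[np.ndarray] = None


@dataclass
class Benchmark:
    """A benchmark system: the SSMEM, its true generating parameters, the
    default observation grid, priors and particle-filter configuration."""

    name: str
    model: SSMEMModel
    times: np.ndarray
    M_default: int
    kappa_true: np.ndarray
    xi_true: np.ndarray
    priors: Priors
    pf_default: PFConfig
    exact_simulator: str = "ssa"
    extras: Dict = field(default_factory=dict)

    def simulate_cell(self, c, kappa, xi, times, rng) -> np.ndarray:
        """One complete synthetic cell: exact latent path + observation noise.

        Returns the observed vector y at the given times.
        """
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        times = np.asarray(times, dtype=float)
        x0 = self.model.initial_state(c)
        if self.exact_simulator == "extrande":
            traj = simulate_extrande(self.model.dynamics, c, kappa, x0, times, rng)
            states = traj.states
        elif self.exact_simulator == "ssa":
            traj = simulate_ssa(self.model.dynamics, c, kappa, x0, times, rng)
            states = traj.states
        elif self.exact_simulator == "ou_exact":
            ou = OUModel(theta1=c[0], theta2=c[1], theta3=c[2], sigma=float(np.atleast_1d(xi)[0]))
            states = ou.simulate(times, rng, x0=float(x0[0]))[:, None]
        else:  # pragma: no cover
            raise ValueError(self.exact_simulator)
        g = np.stack([np.atleast_1d(self.model.obs.g(states[l], t))
                      for l, t in enumerate(times)])
        sigma = np.atleast_1d(np.asarray(xi, dtype=float))
        return g + sigma * rng.standard_normal(g.shape)


# ---------------------------------------------------------------------------
# circadian gene expression
# ---------------------------------------------------------------------------

_CIRC_MU_TRUE = np.log([1.0, 0.3, 1.0, 0.2])  # c1..c4 in 1/h
_CIRC_TAU_TRUE = np.array([0.20, 0.15, 0.20, 0.15])
_CIRC_CORR_34 = 0.5  # translation / protein-decay rates co-vary


def _circadian_omega() -> np.ndarray:
    om = np.diag(_CIRC_TAU_TRUE**2)
    om[2, 3] = om[3, 2] = _CIRC_CORR_34 * _CIRC_TAU_TRUE[2] * _CIRC_TAU_TRUE[3]
    return om


def make_circadian_model(amplitude: float = 0.5, period: float = 24.0) -> Benchmark:
    """Circadian-clock gene expression: mRNA/protein with four reactions and
    transcription rate c1 (1 + amplitude sin(2 pi t / period)).

    All four rates are cell-individual with a full log-normal population law;
    only the protein count is observed, with additive Gaussian noise.
    """
    stoich = np.array([[1, -1, 0, 0], [0, 0, 1, -1]], dtype=float)
    two_pi = 2.0 * np.pi

    def prop(x, c, kappa, t):
        xm, xp = x[..., 0], x[..., 1]
        mod = c[0] * (1.0 + amplitude * np.sin(two_pi * t / period))
        return np.stack(
            [mod * np.ones_like(xm), c[1] * xm, c[2] * xm, c[3] * xp], axis=-1
        )

    @njit(nogil=True)
    def prop_jit(x, c, kappa, t):
        h = np.empty(4)
        h[0] = c[0] * (1.0 + amplitude * np.sin(two_pi * t / period))
        h[1] = c[1] * x[0]
        h[2] = c[2] * x[0]
        h[3] = c[3] * x[1]
        return h

    @njit(nogil=True)
    def prop_jit_into(h, x, c, kappa, t):
        h[0] = c[0] * (1.0 + amplitude * np.sin(two_pi * t / period))
        h[1] = c[1] * x[0]
        h[2] = c[2] * x[0]
        h[3] = c[3] * x[1]

    network = ReactionNetwork(
        stoich=stoich,
        propensity=prop,
        propensity_jit=prop_jit,
        propensity_jit_into=prop_jit_into,
        species_names=["mRNA", "protein"],
        reaction_names=["transcription", "mRNA_decay", "translation", "protein_decay"],
    )
    obs = ObservationModel(
        g=lambda x, t: x[..., 1:2], n_observed=1, linear_P=np.array([[0.0, 1.0]])
    )
    model = SSMEMModel(
        dynamics=network,
        partition=ParameterPartition(names_c=["c1", "c2", "c3", "c4"], names_kappa=[],
                                     names_xi=["sigma"]),
        population=PopulationLaw(_CIRC_MU_TRUE, _circadian_omega()),
        obs=obs,
        x0=np.array([0.0, 0.0]),
        name="circadian",
    )
    priors = Priors(
        niw=NIWPrior(mu0=np.array([0.0, -1.0, 0.0, -1.0]), lambda0=0.2,
                     psi0=0.04 * (8.0 - 4.0 - 1.0) * np.eye(4), nu0=8.0),
        xi_mean=np.log([1.5]), xi_sd=np.array([0.5]),
    )
    return Benchmark(
        name="circadian", model=model,
        times=np.linspace(0.0, 72.0, 26)[1:],
        M_default=40,
        kappa_true=np.zeros(0), xi_true=np.array([2.0]),
        priors=priors,
        pf_default=PFConfig(n_particles=40, kind="bootstrap", integrator="extrande", rho=0.0),
        exact_simulator="extrande",
        extras={"amplitude": amplitude, "period": period},
    )


# ---------------------------------------------------------------------------
# Schlogl bistable network
# ---------------------------------------------------------------------------

# Defaults put the deterministic fixed points near 20 / 90 (unstable ~50) so
# that cells at these copy numbers switch stochastically within the horizon.
_SCHLOGL_C1_TRUE = 0.032   # 2X -> 3X
_SCHLOGL_TAU_TRUE = 0.15
_SCHLOGL_KAPPA_TRUE = np.array([6.0e-4, 9.0])  # c2 (3X -> 2X), c3 (0 -> X)
_SCHLOGL_C4 = 0.73         # X -> 0, assumed known


def make_schlogl_model(convention: str = "combinatorial", c4: float = _SCHLOGL_C4) -> Benchmark:
    """The Schlogl model: one species, four reactions, stochastic
    bistability.  c1 is cell-varying (log-normal), (c2, c3) are
    cell-constant and c4 is known.

    ``convention`` selects the propensity form for the higher-order
    reactions: ``combinatorial`` uses c1 x(x-1)/2 and c2 x(x-1)(x-2)/6,
    ``power`` uses c1 x^2/2 and c2 x^3/6.
    """
    if convention not in ("combinatorial", "power"):
        raise ValueError("convention must be 'combinatorial' or 'power'")
    comb = convention == "combinatorial"
    stoich = np.array([[1, -1, 1, -1]], dtype=float)

    def prop(x, c, kappa, t):
        xx = x[..., 0]
        if comb:
            h1 = c[0] * xx * (xx - 1.0) / 2.0
            h2 = kappa[0] * xx * (xx - 1.0) * (xx - 2.0) / 6.0
        else:
            h1 = c[0] * xx**2 / 2.0
            h2 = kappa[0] * xx**3 / 6.0
        h3 = kappa[1] * np.ones_like(xx)
        h4 = c4 * xx
        return np.stack([np.maximum(h1, 0.0), np.maximum(h2, 0.0), h3, h4], axis=-1)

    @njit(nogil=True)
    def prop_jit(x, c, kappa, t):
        h = np.empty(4)
        xx = x[0]
        if comb:
            h[0] = c[0] * xx * (xx - 1.0) / 2.0
            h[1] = kappa[0] * xx * (xx - 1.0) * (xx - 2.0) / 6.0
        else:
            h[0] = c[0] * xx * xx / 2.0
            h[1] = kappa[0] * xx * xx * xx / 6.0
        if h[0] < 0.0:
            h[0] = 0.0
        if h[1] < 0.0:
            h[1] = 0.0
        h[2] = kappa[1]
        h[3] = c4 * xx
        return h

    @njit(nogil=True)
    def moments_jit(X, c, kappa, t):
        N = X.shape[0]
        a = np.empty(N)
        G = np.empty(N)
        for n in range(N):
            xx = X[n] if X[n] > 0.0 else 0.0
            if comb:
                h1 = c[0] * xx * (xx - 1.0) / 2.0
                h2 = kappa[0] * xx * (xx - 1.0) * (xx - 2.0) / 6.0
                if h1 < 0.0:
                    h1 = 0.0
                if h2 < 0.0:
                    h2 = 0.0
            else:
                h1 = c[0] * xx * xx / 2.0
                h2 = kappa[0] * xx * xx * xx / 6.0
            h3 = kappa[1]
            h4 = c4 * xx
            a[n] = h1 - h2 + h3 - h4
            G[n] = h1 + h2 + h3 + h4
        return a, G

    network = ReactionNetwork(
        stoich=stoich, propensity=prop, propensity_jit=prop_jit,
        langevin_moments_jit=moments_jit,
        species_names=["X"],
        reaction_names=["autocatalysis", "reverse_autocatalysis", "influx", "decay"],
    )
    obs = ObservationModel(g=lambda x, t: x[..., 0:1], n_observed=1,
                           linear_P=np.array([[1.0]]))
    model = SSMEMModel(
        dynamics=network,
        partition=ParameterPartition(names_c=["c1"], names_kappa=["c2", "c3"],
                                     names_xi=["sigma"]),
        population=PopulationLaw(np.log([_SCHLOGL_C1_TRUE]),
                                 np.array([[_SCHLOGL_TAU_TRUE**2]])),
        obs=obs,
        x0=np.array([20.0]),
        name="schlogl",
    )
    priors = Priors(
        niw=NIWPrior(mu0=np.array([np.log(0.03)]), lambda0=0.2,
                     psi0=np.array([[0.04 * (4.0 - 1.0 - 1.0)]]), nu0=4.0),
        kappa_mean=np.array([-7.0, 2.0]), kappa_sd=np.array([0.5, 0.5]),
        xi_mean=np.log([1.5]), xi_sd=np.array([0.5]),
    )
    return Benchmark(
        name="schlogl", model=model,
        times=np.linspace(1.0, 40.0, 40),
        M_default=150,
        kappa_true=_SCHLOGL_KAPPA_TRUE.copy(), xi_true=np.array([2.0]),
        priors=priors,
        pf_default=PFConfig(n_particles=10, kind="guided_mdb", integrator="langevin",
                            dt=0.2, rho=0.999),
        exact_simulator="ssa",
        extras={"c4": c4, "convention": convention},
    )


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck
# ---------------------------------------------------------------------------

_OU_MU_TRUE = np.log([0.8, 5.0, 1.0])  # theta1, theta2, theta3
_OU_TAU_TRUE = np.array([0.15, 0.10, 0.15])


def make_ou_model() -> Benchmark:
    """The OU benchmark dX = theta1 (theta2 - X) dt + theta3 dW, y = x + eps.

    (theta1, theta2, theta3) are cell-varying log-normal; sigma is the error
    parameter.  Data generation uses the exact discrete transition; the
    particle filter uses the Euler (Langevin) path.  Each cell starts at its
    own stationary mean theta2 (a deterministic function of c).
    """

    def drift(x, c, kappa, t):
        return c[0] * (c[1] - x)

    def diffusion(x, c, kappa, t):
        return c[2] * np.ones_like(x)

    @njit(nogil=True)
    def moments_jit(X, c, kappa, t):
        a = c[0] * (c[1] - X)
        G = np.full(X.shape[0], c[2] * c[2])
        return a, G

    dynamics = SDEDynamics(n_species=1, drift=drift, diffusion=diffusion,
                           species_names=["X"], langevin_moments_jit=moments_jit)
    obs = ObservationModel(g=lambda x, t: x[..., 0:1], n_observed=1,
                           linear_P=np.array([[1.0]]))
    model = SSMEMModel(
        dynamics=dynamics,
        partition=ParameterPartition(names_c=["theta1", "theta2", "theta3"],
                                     names_kappa=[], names_xi=["sigma"]),
        population=PopulationLaw(_OU_MU_TRUE, np.diag(_OU_TAU_TRUE**2)),
        obs=obs,
        x0=lambda c: np.array([c[1]]),
        name="ou",
    )
    priors = Priors(
        niw=NIWPrior(mu0=np.array([-0.5, 1.5, -0.2]), lambda0=1.0,
                     psi0=0.04 * (10.0 - 3.0 - 1.0) * np.eye(3), nu0=10.0),
        xi_mean=np.log([0.5]), xi_sd=np.array([0.7]),
    )
    return Benchmark(
        name="ou", model=model,
        times=np.linspace(0.5, 10.0, 20),
        M_default=40,
        kappa_true=np.zeros(0), xi_true=np.array([0.3]),
        priors=priors,
        pf_default=PFConfig(n_particles=100, kind="bootstrap", integrator="langevin",
                            dt=0.1, rho=0.0),
        exact_simulator="ou_exact",
    )


_FACTORIES = {
    "circadian": make_circadian_model,
    "schlogl": make_schlogl_model,
    "ou": make_ou_model,
}


def get_benchmark(name: str, **kwargs) -> Benchmark:
    try:
        return _FACTORIES[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(_FACTORIES)}")


def generate_dataset(
    spec: BenchmarkSpec,
    rng: Optional[Union[int, np.random.Generator]] = None,
):
    """Generate one multi-cell dataset from a benchmark recipe.

    Per cell: draw c^(i) from the population law, simulate the latent path
    with the system's exact simulator, add observation noise.  Returns
    ``(Dataset, truth)`` where ``truth`` records every latent parameter
    (the per-cell c, kappa, xi, mu, Omega) for recovery scoring.
    """
    bench = get_benchmark(spec.name)
    times = np.asarray(spec.times, float) if spec.times is not None else bench.times
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    from .network import sample_individual_parameters

    C = sample_individual_parameters(bench.model.population, spec.M, rng)
    individuals = []
    for i in range(spec.M):
        y = bench.simulate_cell(C[i], bench.kappa_true, bench.xi_true, times, rng)
        individuals.append(Individual(times, y))
    truth = {
        "c": C,
        "kappa": bench.kappa_true.copy(),
        "xi": bench.xi_true.copy(),
        "mu": bench.model.population.mu.copy(),
        "omega": bench.model.population.omega.copy(),
    }
    return Dataset(individuals), truth
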