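"""Model definition layer: reaction networks, parameter partition, population
law, observation model and the assembled state-space mixed-effects model.

A state-space mixed-effects model (SSMEM) couples, per cell ``i``, a latent
Markov process (a chemical reaction network or an SDE) driven by
cell-individual rate constants ``c^(i)``, cell-constant parameters ``kappa``
and an observation layer ``y = g(x, t) + eps`` with error parameters ``xi``.
Between-cell (extrinsic) variability is modelled hierarchically by a
log-normal population law ``c^(i) ~ LN(mu, Omega)`` with population
parameters ``eta = (mu, Omega)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "ModelDefinitionError",
    "ReactionNetwork",
    "SDEDynamics",
    "ParameterPartition",
    "PopulationLaw",
    "NIWPrior",
    "ObservationModel",
    "SSMEMModel",
    "evaluate_propensities",
    "sample_individual_parameters",
    "observation_logdensity",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class ModelDefinitionError(ValueError):
    """Raised when a user-supplied model hook violates its contract."""


@dataclass
class ReactionNetwork:
    """A chemical reaction network: stoichiometry plus propensity hook.

    Parameters
    ----------
    stoich
        Integer matrix of shape ``(n_species, n_reactions)``; column ``j``
        is the net state change when reaction ``j`` fires.
    propensity
        Callable ``(x, c, kappa, t) -> h`` returning nonnegative reaction
        intensities.  Must broadcast: for ``x`` of shape ``(..., d)`` it
        returns shape ``(..., R)`` (vectorised evaluation over particles).
    propensity_jit
        Optional numba ``@njit`` dispatcher with the scalar signature
        ``(x: float64[:], c: float64[:], kappa: float64[:], t: float64)
        -> float64[:]``.  When present, SSA/Extrande inner loops run
        compiled; otherwise a pure-Python path is used.
    """

    stoich: np.ndarray
    propensity: Callable[..., np.ndarray]
    species_names: Sequence[str] = ()
    reaction_names: Sequence[str] = ()
    propensity_jit: Optional[Callable] = None
    #: optional compiled in-place variant ``(h, x, c, kappa, t) -> None``
    #: writing into a preallocated length-R buffer; avoids per-call
    #: allocation in the hottest filter kernels (derived automatically from
    #: ``propensity_jit`` when absent).
    propensity_jit_into: Optional[Callable] = None
    #: optional compiled ``(X, c, kappa, t) -> (drift, diffusion covariance)``
    #: hook over an (N,) particle vector; enables the fast scalar-state
    #: Langevin filter kernel.
    langevin_moments_jit: Optional[Callable] = None

    def __post_init__(self) -> None:
        self.stoich = np.asarray(self.stoich)
        if self.stoich.ndim != 2:
            raise ModelDefinitionError("stoich must be a (species x reactions) matrix")
        if not self.species_names:
            self.species_names = [f"x{k}" for k in range(self.n_species)]
        if not self.reaction_names:
            self.reaction_names = [f"r{j}" for j in range(self.n_reactions)]

    @property
    def n_species(self) -> int:
        return self.stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]


@dataclass
class SDEDynamics:
    """Latent dynamics given directly as an Ito SDE (diagonal noise).

    Used for models that are not naturally written as reaction networks,
    e.g. the Ornstein-Uhlenbeck benchmark.  ``drift`` and ``diffusion``
    (the diffusion *standard deviation* per component) broadcast over a
    leading particle axis like :class:`ReactionNetwork.propensity`.
    """

    n_species: int
    drift: Callable[..., np.ndarray]
    diffusion: Callable[..., np.ndarray]
    species_names: Sequence[str] = ()
    langevin_moments_jit: Optional[Callable] = None

    def __post_init__(self) -> None:
        if not self.species_names:
            self.species_names = [f"x{k}" for k in range(self.n_species)]


Dynamics = Union[ReactionNetwork, SDEDynamics]


@dataclass
class ParameterPartition:
    """Partition of the unknowns into cell-individual ``c``, cell-constant
    ``kappa`` and error parameters ``xi``, with the sampling-scale transform
    per coordinate (``log`` for positive rates, ``identity`` otherwise)."""

    names_c: Sequence[str]
    names_kappa: Sequence[str] = ()
    names_xi: Sequence[str] = ("sigma",)
    transform_c: Sequence[str] = ()
    transform_kappa: Sequence[str] = ()
    transform_xi: Sequence[str] = ()

    def __post_init__(self) -> None:
        if not self.transform_c:
            self.transform_c = ["log"] * self.dim_c
        if not self.transform_kappa:
            self.transform_kappa = ["log"] * self.dim_kappa
        if not self.transform_xi:
            self.transform_xi = ["log"] * self.dim_xi
        for tf in (*self.transform_c, *self.transform_kappa, *self.transform_xi):
            if tf not in ("log", "identity"):
                raise ModelDefinitionError(f"unknown transform {tf!r}")

    @property
    def dim_c(self) -> int:
        return len(self.names_c)

    @property
    def dim_kappa(self) -> int:
        return len(self.names_kappa)

    @property
    def dim_xi(self) -> int:
        return len(self.names_xi)


def to_unconstrained(values: np.ndarray, transforms: Sequence[str]) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    out = values.copy()
    for k, tf in enumerate(transforms):
        if tf == "log":
            out[..., k] = np.log(values[..., k])
    return out


def from_unconstrained(theta: np.ndarray, transforms: Sequence[str]) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    out = theta.copy()
    for k, tf in enumerate(transforms):
        if tf == "log":
            out[..., k] = np.exp(theta[..., k])
    return out


@dataclass
class NIWPrior:
    """Normal-Inverse-Wishart hyperprior on (mu, Omega)."""

    mu0: np.ndarray
    lambda0: float
    psi0: np.ndarray
    nu0: float

    def __post_init__(self) -> None:
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        self.psi0 = np.atleast_2d(np.asarray(self.psi0, dtype=float))
        p = self.mu0.shape[0]
        if self.psi0.shape != (p, p):
            raise ModelDefinitionError("psi0 shape must match mu0")
        if self.nu0 <= p - 1:
            raise ModelDefinitionError("nu0 must exceed dim - 1")


@dataclass
class PopulationLaw:
    """Log-normal population law c^(i) ~ LN(mu, Omega).

    ``family`` is ``lognormal_full`` (free covariance) or ``lognormal_diag``
    (Omega constrained diagonal).  ``log c^(i)`` is multivariate normal with
    mean ``mu`` and covariance ``Omega``; ``tau = sqrt(diag(Omega))`` is the
    between-cell scale reported in summaries.
    """

    mu: np.ndarray
    omega: np.ndarray
    family: str = "lognormal_full"
    hyperprior: Optional[NIWPrior] = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        p = self.dim
        if self.omega.shape != (p, p):
            raise ModelDefinitionError("omega must be square matching mu")
        if self.family not in ("lognormal_full", "lognormal_diag"):
            raise ModelDefinitionError(f"unknown family {self.family!r}")
        if self.family == "lognormal_diag":
            self.omega = np.diag(np.diag(self.omega))
        _assert_positive_definite(self.omega)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]

    @property
    def tau(self) -> np.ndarray:
        return np.sqrt(np.diag(self.omega))

    def logpdf_log(self, v: np.ndarray) -> np.ndarray:
        """Gaussian log-density of v = log c under (mu, Omega)."""
        return stats.multivariate_normal.logpdf(v, mean=self.mu, cov=self.omega)


def _assert_positive_definite(omega: np.ndarray) -> None:
    # degenerate Omega = 0 (point-mass population) is tolerated for testing
    if np.allclose(omega, 0.0):
        return
    try:
        np.linalg.cholesky(omega + 0.0)
    except np.linalg.LinAlgError as exc:
        raise ModelDefinitionError("population covariance is not positive definite") from exc


@dataclass
class ObservationModel:
    """Observation layer ``y_l = g(x_l, t_l) + eps_l``, additive Gaussian.

    ``g`` broadcasts over the particle axis; ``linear_P`` optionally exposes
    the selection/linear matrix ``P`` with ``g(x, t) = P x``, which the
    guided (modified diffusion bridge) filter requires.
    """

    g: Callable[..., np.ndarray]
    n_observed: int = 1
    error: str = "gaussian_additive"
    linear_P: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.error != "gaussian_additive":
            raise ModelDefinitionError(f"unsupported error model {self.error!r}")
        if self.linear_P is not None:
            self.linear_P = np.atleast_2d(np.asarray(self.linear_P, dtype=float))

    def logdensity(self, y: np.ndarray, x: np.ndarray, t: float, xi: np.ndarray) -> np.ndarray:
        return observation_logdensity(self, y, x, t, xi)


@dataclass
class SSMEMModel:
    """A complete state-space mixed-effects model."""

    dynamics: Dynamics
    partition: ParameterPartition
    population: PopulationLaw
    obs: ObservationModel
    x0: Union[np.ndarray, Callable[[np.ndarray], np.ndarray]] = field(default=None)
    name: str = "ssmem"

    def __post_init__(self) -> None:
        if self.population.dim != self.partition.dim_c:
            raise ModelDefinitionError("population law dimension must equal dim_c")
        if self.x0 is None:
            raise ModelDefinitionError("an initial-state rule (array or callable of c) is required")
        if not callable(self.x0):
            self.x0 = np.asarray(self.x0, dtype=float)

    def initial_state(self, c: np.ndarray) -> np.ndarray:
        """Initial latent state; cell-varying initial values are encoded as
        designated coordinates of ``c`` via a callable rule."""
        if callable(self.x0):
            return np.asarray(self.x0(c), dtype=float)
        return np.asarray(self.x0, dtype=float)


def evaluate_propensities(
    network: ReactionNetwork,
    x: np.ndarray,
    c: np.ndarray,
    kappa: np.ndarray,
    t: float,
) -> np.ndarray:
    """Evaluate the propensity vector h(x, c, t), validating the contract.

    Raises :class:`ModelDefinitionError` naming the offending reaction if
    any propensity is non-finite or negative.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(network.propensity(x, np.asarray(c, float), np.asarray(kappa, float), float(t)), dtype=float)
    if h.shape[-1] != network.n_reactions:
        raise ModelDefinitionError(
            f"propensity returned {h.shape[-1]} values, expected {network.n_reactions}"
        )
    bad = ~np.isfinite(h) | (h < 0)
    if np.any(bad):
        j = int(np.argwhere(bad)[0][-1])
        name = network.reaction_names[j]
        raise ModelDefinitionError(
            f"propensity of reaction {j} ({name}) is invalid at x={x!r}, t={t}"
        )
    return h


def sample_individual_parameters(
    pop: PopulationLaw, M: int, rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """Draw M iid cell-individual parameter vectors c^(i) ~ LN(mu, Omega).

    Returns an (M, dim_c) matrix on the natural (positive) scale.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    _assert_positive_definite(pop.omega)
    if np.allclose(pop.omega, 0.0):
        v = np.tile(pop.mu, (M, 1))
    else:
        v = rng.multivariate_normal(pop.mu, pop.omega, size=M, method="cholesky")
    return np.exp(v)


def observation_logdensity(
    obs: ObservationModel, y: np.ndarray, x: np.ndarray, t: float, xi: np.ndarray
) -> np.ndarray:
    """Gaussian observation log-density sum_q log N(y_q; g(x,t)_q, sigma_q^2).

    ``x`` may carry a leading particle axis; the return broadcasts with it.
    ``xi`` holds the error scales sigma (natural scale, all > 0).
    """
    sigma = np.atleast_1d(np.asarray(xi, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("observation error scale sigma must be positive")
    mean = np.asarray(obs.g(np.asarray(x, float), float(t)), dtype=float)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    resid = y - mean
    ll = -0.5 * (_LOG2PI + 2.0 * np.log(sigma) + (resid / sigma) ** 2)
    return ll.sum(axis=-1)
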