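import numpy as np
import pytest
from numba import njit

from ssmem import (
    ObservationModel,
    ParameterPartition,
    PopulationLaw,
    ReactionNetwork,
    SDEDynamics,
    SSMEMModel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _birth_death_prop(x, c, kappa, t):
    xx = x[..., 0]
    return np.stack([c[0] * np.ones_like(xx), c[1] * xx], axis=-1)


@njit(nogil=True)
def _birth_death_prop_jit(x, c, kappa, t):
    h = np.empty(2)
    h[0] = c[0]
    h[1] = c[1] * x[0]
    return h


@pytest.fixture(scope="session")
def birth_death():
    """Birth-death network: 0 -> X at rate c1, X -> 0 at rate c2 x."""
    return ReactionNetwork(
        stoich=np.array([[1, -1]], dtype=float),
        propensity=_birth_death_prop,
        propensity_jit=_birth_death_prop_jit,
        species_names=["X"],
        reaction_names=["birth", "death"],
    )


@pytest.fixture(scope="session")
def zero_noise_sde_model():
    """Deterministic (zero-diffusion) scalar SDE observed directly: the
    degenerate case where a single-particle filter is exact."""
    dyn = SDEDynamics(
        n_species=1,
        drift=lambda x, c, kappa, t: -c[0] * x,
        diffusion=lambda x, c, kappa, t: np.zeros_like(x),
    )
    return SSMEMModel(
        dynamics=dyn,
        partition=ParameterPartition(names_c=["rate"], names_xi=["sigma"]),
        population=PopulationLaw(np.zeros(1), np.eye(1) * 0.01),
        obs=ObservationModel(g=lambda x, t: x[..., 0:1], linear_P=np.array([[1.0]])),
        x0=np.array([5.0]),
    )
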