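"""Simulator correctness: absorbing states, analytic moments, determinism."""

import numpy as np
import pytest
from numba import njit

import ssmem
from ssmem import (
    ExtrandeBound,
    ReactionNetwork,
    SDEDynamics,
    SimulationError,
    simulate_extrande,
    simulate_langevin,
    simulate_ssa,
    simulate_tauleap,
)
from ssmem.simulate import tauleap_substep


def _pure_death():
    @njit
    def prop_jit(x, c, kappa, t):
        h = np.empty(1)
        h[0] = c[0] * x[0]
        return h

    return ReactionNetwork(
        stoich=np.array([[-1.0]]),
        propensity=lambda x, c, k, t: (c[0] * x[..., 0])[..., None],
        propensity_jit=prop_jit,
    )


class TestSSA:
    def test_absorbing_state(self, birth_death, rng):
        traj = simulate_ssa(birth_death, np.array([0.0, 0.0]), np.zeros(0),
                            np.array([3.0]), np.linspace(1, 5, 5), rng)
        assert np.all(traj.states == 3.0)

    def test_pure_death_analytic_mean(self, rng):
        net = _pure_death()
        n = 3000
        finals = np.array([
            simulate_ssa(net, np.array([1.0]), np.zeros(0), np.array([50.0]),
                         np.array([1.0]), rng).states[-1, 0]
            for _ in range(n)
        ])
        expected = 50.0 * np.exp(-1.0)
        # binomial thinning: var = 50 p (1-p)
        se = np.sqrt(50 * np.exp(-1) * (1 - np.exp(-1)) / n)
        assert abs(finals.mean() - expected) < 3 * se

    def test_integer_nonnegative_states(self, birth_death, rng):
        traj = simulate_ssa(birth_death, np.array([5.0, 0.5]), np.zeros(0),
                            np.array([10.0]), np.linspace(0.5, 10, 20), rng)
        assert np.all(traj.states >= 0)
        assert np.all(traj.states == np.round(traj.states))

    def test_seed_reproducibility(self, birth_death):
        t = np.linspace(0.5, 5, 10)
        a = simulate_ssa(birth_death, np.array([5.0, 0.5]), np.zeros(0), np.array([10.0]), t, 7)
        b = simulate_ssa(birth_death, np.array([5.0, 0.5]), np.zeros(0), np.array([10.0]), t, 7)
        assert np.array_equal(a.states, b.states)


class TestExtrande:
    def test_reduces_to_ssa_for_constant_rates(self, birth_death, rng):
        from scipy.stats import ks_2samp

        t = np.array([2.0])
        n = 2000
        c = np.array([5.0, 0.5])
        ssa = [simulate_ssa(birth_death, c, np.zeros(0), np.array([10.0]), t, rng).states[-1, 0]
               for _ in range(n)]
        ext = [simulate_extrande(birth_death, c, np.zeros(0), np.array([10.0]), t, rng).states[-1, 0]
               for _ in range(n)]
        assert ks_2samp(ssa, ext).pvalue > 0.01

    def test_inflated_bound_same_distribution(self, birth_death, rng):
        """Thinning correctness does not depend on the bound's tightness."""
        from scipy.stats import ks_2samp

        t = np.array([2.0])
        c = np.array([5.0, 0.5])
        tight = [simulate_extrande(birth_death, c, np.zeros(0), np.array([10.0]), t,
                                   rng).states[-1, 0] for _ in range(1500)]
        loose = [simulate_extrande(birth_death, c, np.zeros(0), np.array([10.0]), t, rng,
                                   bound=ExtrandeBound(constant=150.0)).states[-1, 0]
                 for _ in range(1500)]
        assert ks_2samp(tight, loose).pvalue > 0.01

    def test_bound_violation_reports_time_and_deficit(self, birth_death, rng):
        with pytest.raises(SimulationError, match="bound violated"):
            simulate_extrande(birth_death, np.array([50.0, 1.0]), np.zeros(0),
                              np.array([10.0]), np.array([5.0]), rng,
                              bound=ExtrandeBound(constant=1.0))

    def test_circadian_mean_trajectory_period(self):
        """The population-mean protein trajectory of the clock-driven model
        oscillates with a dominant 24 h period."""
        bench = ssmem.make_circadian_model()
        rng = np.random.default_rng(42)
        times = np.linspace(1.0, 96.0, 96)
        n_cells = 150
        c = np.exp(bench.model.population.mu)
        Y = np.stack([
            simulate_extrande(bench.model.dynamics, c, np.zeros(0),
                              np.array([0.0, 0.0]), times, rng).states[:, 1]
            for _ in range(n_cells)
        ])
        mean = Y.mean(axis=0)
        # discard the transient first day, Fourier-analyse the rest
        tail = mean[24:] - mean[24:].mean()
        power = np.abs(np.fft.rfft(tail)) ** 2
        freqs = np.fft.rfftfreq(tail.size, d=1.0)
        dominant = freqs[1:][np.argmax(power[1:])]
        assert abs(1.0 / dominant - 24.0) < 4.0


class TestTauLeap:
    def test_zero_propensity_constant(self, rng):
        net = _pure_death()
        traj = simulate_tauleap(net, np.array([1.0]), np.zeros(0), np.array([0.0]),
                                np.array([1.0, 2.0]), dt=0.1, rng=rng)
        assert np.all(traj.states == 0.0)

    def test_zero_order_closed_form_any_dt(self, rng):
        """0 -> X at rate 5 over t=2: X ~ Poisson(10) exactly at any step."""
        net = ReactionNetwork(stoich=np.array([[1.0]]),
                              propensity=lambda x, c, k, t: np.broadcast_to(
                                  c[0], x.shape[:-1] + (1,)).astype(float))
        n = 4000
        X = np.zeros((n, 1))
        X = tauleap_substep(net, X, np.array([5.0]), np.zeros(0), 0.0, 2.0, rng=rng)
        lam = 10.0
        assert abs(X.mean() - lam) < 3 * np.sqrt(lam / n)
        assert abs(X.var() - lam) < 3 * lam * np.sqrt(2.0 / n)

    def test_dt_error(self, birth_death, rng):
        with pytest.raises(ValueError):
            simulate_tauleap(birth_death, np.ones(2), np.zeros(0), np.array([1.0]),
                             np.array([1.0]), dt=-0.1, rng=rng)

    def test_linear_birth_death_small_dt_moments(self, rng):
        """At small dt the Poisson leap matches the exact (SSA-level)
        moments of the linear birth-death process."""
        net_bd = ReactionNetwork(
            stoich=np.array([[1.0, -1.0]]),
            propensity=lambda x, c, k, t: np.stack(
                [np.broadcast_to(c[0], x.shape[:-1]).astype(float), c[1] * x[..., 0]], axis=-1),
        )
        c = np.array([10.0, 1.0])
        n = 3000
        X = np.full((n, 1), 20.0)
        dt = 0.002
        for s in range(500):  # t = 1
            X = tauleap_substep(net_bd, X, c, np.zeros(0), s * dt, dt, rng=rng)
        # analytic: mean = 10 + 10 e^{-1}; var of (immigration-death)
        mean_exact = 10.0 + 10.0 * np.exp(-1.0)
        var_exact = 10.0 * (1 - np.exp(-1)) + 20.0 * np.exp(-1) * (1 - np.exp(-1))
        assert abs(X.mean() - mean_exact) < 3 * np.sqrt(var_exact / n)
        assert abs(X.var() - var_exact) < 4 * var_exact * np.sqrt(2.0 / n)


class TestLangevin:
    def test_drift_only_matches_euler_ode(self, rng):
        dyn = SDEDynamics(n_species=1,
                          drift=lambda x, c, k, t: -c[0] * x,
                          diffusion=lambda x, c, k, t: np.zeros_like(x))
        traj = simulate_langevin(dyn, np.array([1.0]), np.zeros(0), np.array([5.0]),
                                 np.array([1.0]), dt=0.01, rng=rng)
        # deterministic Euler recursion
        x = 5.0
        for _ in range(100):
            x -= 0.01 * x
        assert np.isclose(traj.states[-1, 0], x)

    def test_linear_birth_death_moments(self, rng):
        net_bd = ReactionNetwork(
            stoich=np.array([[1.0, -1.0]]),
            propensity=lambda x, c, k, t: np.stack(
                [np.broadcast_to(c[0], x.shape[:-1]).astype(float),
                 c[1] * np.maximum(x[..., 0], 0.0)], axis=-1),
        )
        c = np.array([50.0, 1.0])
        n = 2000
        finals = np.array([
            simulate_langevin(net_bd, c, np.zeros(0), np.array([50.0]),
                              np.array([1.0]), dt=0.01, rng=rng).states[-1, 0]
            for _ in range(n)
        ])
        var_exact = 50.0 * (1 - np.exp(-2.0))  # fixed x0 at the stationary mean, t = 1
        assert abs(finals.mean() - 50.0) < 3 * np.sqrt(var_exact / n)
        assert abs(finals.var() - var_exact) < 0.1 * var_exact  # within 10% of the jump-process variance

    def test_nonfinite_state_raises_with_step_index(self, rng):
        dyn = SDEDynamics(n_species=1,
                          drift=lambda x, c, k, t: x**3 * 1e6,
                          diffusion=lambda x, c, k, t: np.ones_like(x))
        with pytest.raises(SimulationError, match="step"):
            simulate_langevin(dyn, np.ones(1), np.zeros(0), np.array([10.0]),
                              np.array([5.0]), dt=0.5, rng=rng)

    def test_seed_reproducibility(self, rng):
        dyn = SDEDynamics(n_species=1,
                          drift=lambda x, c, k, t: -x,
                          diffusion=lambda x, c, k, t: np.ones_like(x))
        a = simulate_langevin(dyn, np.ones(1), np.zeros(0), np.array([1.0]),
                              np.array([1.0]), dt=0.1, rng=3)
        b = simulate_langevin(dyn, np.ones(1), np.zeros(0), np.array([1.0]),
                              np.array([1.0]), dt=0.1, rng=3)
        assert np.array_equal(a.states, b.states)
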