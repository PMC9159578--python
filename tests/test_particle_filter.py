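"""Particle filter properties: configuration contracts, auxiliary-number
refresh, resampling, degenerate filters and path equivalences."""

import numpy as np
import pytest

import ssmem
from ssmem import (
    PFConfig,
    make_auxiliary,
    pf_loglik,
    refresh_auxiliary,
    systematic_resample,
)
from ssmem.network import observation_logdensity


class TestPFConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho": 0.5, "integrator": "ssa"},
            {"rho": 1.0},
            {"kind": "guided_mdb", "integrator": "tauleap"},
            {"ess_threshold": 0.0},
            {"n_particles": 0},
            {"kind": "nope"},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PFConfig(**kwargs)

    def test_guided_requires_linear_observation(self, rng):
        bench = ssmem.make_ou_model()
        model = bench.model
        # strip the linear structure
        import dataclasses
        obs = dataclasses.replace(model.obs, linear_P=None)
        model2 = dataclasses.replace(model, obs=obs)
        cfg = PFConfig(n_particles=8, kind="guided_mdb", integrator="langevin", dt=0.1)
        u = make_auxiliary(model2, bench.times, cfg, rng)
        with pytest.raises(ValueError, match="linear"):
            ssmem.pf_loglik_guided_mdb(model2, bench.times, np.zeros(20), np.ones(3),
                                       np.zeros(0), np.array([0.3]), u, cfg)


class TestAuxiliaryRefresh:
    def test_rho_zero_independent(self, rng):
        u = ssmem.AuxiliaryNumbers(rng.standard_normal((100, 10, 5, 2)), rng.standard_normal(10))
        u2 = refresh_auxiliary(u, 0.0, rng)
        r = np.corrcoef(u.normals.ravel(), u2.normals.ravel())[0, 1]
        assert abs(r) < 0.03

    def test_high_rho_correlation_and_marginal(self, rng):
        n = 10**6
        u = ssmem.AuxiliaryNumbers(rng.standard_normal((n, 1, 1, 1)), rng.standard_normal(1))
        u2 = refresh_auxiliary(u, 0.999, rng)
        r = np.corrcoef(u.normals.ravel(), u2.normals.ravel())[0, 1]
        se = (1 - 0.999**2) / np.sqrt(n)
        assert abs(r - 0.999) < 3 * max(se, 1e-5)
        assert abs(u2.normals.std() - 1.0) < 0.005  # N(0,1) marginal preserved

    def test_rho_one_excluded(self, rng):
        u = ssmem.AuxiliaryNumbers(rng.standard_normal((2, 1, 1, 1)), rng.standard_normal(1))
        with pytest.raises(ValueError):
            refresh_auxiliary(u, 1.0, rng)


class TestSystematicResample:
    def test_uniform_weights_identity_permutation(self):
        N = 16
        idx = systematic_resample(np.full(N, 1.0 / N), 0.3)
        assert sorted(idx) == list(range(N))

    def test_point_mass(self):
        w = np.zeros(8)
        w[0] = 1.0
        assert np.all(systematic_resample(w, 0.77) == 0)

    def test_offspring_expectation_unbiased(self, rng):
        w = rng.dirichlet(np.ones(8))
        n_rep = 20000
        counts = np.zeros(8)
        for u in rng.random(n_rep):
            idx = systematic_resample(w, u)
            counts += np.bincount(idx, minlength=8)
        freq = counts / (n_rep * 8)
        assert np.all(np.abs(freq - w) < 4.0 / np.sqrt(n_rep))


class TestFilterDegenerateAndEquivalence:
    def test_zero_noise_single_particle_is_exact(self, zero_noise_sde_model, rng):
        """With deterministic dynamics and N=1, the filter value equals the
        sum of observation log-densities along the deterministic path."""
        model = zero_noise_sde_model
        times = np.linspace(0.5, 2.0, 4)
        c = np.array([0.8])
        xi = np.array([0.5])
        # deterministic Euler path
        x, expected, t_prev = 5.0, 0.0, 0.0
        dt = 0.05
        ys = np.array([4.0, 3.0, 2.5, 2.0])
        for l, t in enumerate(times):
            n_sub = int(round((t - t_prev) / dt))
            for _ in range(n_sub):
                x -= c[0] * x * dt
            expected += observation_logdensity(model.obs, ys[l : l + 1], np.array([x]),
                                               t, xi)
            t_prev = t
        cfg = PFConfig(n_particles=1, integrator="langevin", dt=dt)
        u = make_auxiliary(model, times, cfg, rng)
        est = pf_loglik(model, times, ys, c, np.zeros(0), xi, u, cfg)
        assert np.isclose(est.value, expected)
        assert np.isclose(est.increments.sum(), est.value)

    def test_compiled_and_generic_paths_agree(self, rng):
        """Same auxiliary numbers through the numba kernel and the numpy
        implementation give the same estimate (both filter kinds)."""
        bench = ssmem.make_ou_model()
        times = bench.times
        c = np.exp(bench.model.population.mu)
        y = bench.simulate_cell(c, np.zeros(0), bench.xi_true, times, rng).ravel()
        for kind in ("bootstrap", "guided_mdb"):
            cfg = PFConfig(n_particles=32, kind=kind, integrator="langevin", dt=0.1)
            u = make_auxiliary(bench.model, times, cfg, rng)
            fast = pf_loglik(bench.model, times, y, c, np.zeros(0), bench.xi_true, u, cfg).value
            import dataclasses
            dyn = dataclasses.replace(bench.model.dynamics, langevin_moments_jit=None)
            model2 = dataclasses.replace(bench.model, dynamics=dyn)
            slow = pf_loglik(model2, times, y, c, np.zeros(0), bench.xi_true, u, cfg).value
            assert np.isclose(fast, slow, rtol=1e-9), kind

    def test_guided_decays_to_bootstrap_for_uninformative_data(self, rng):
        """As sigma -> infinity the bridge proposal loses the data pull and
        the guided estimate equals the bootstrap estimate on shared draws."""
        bench = ssmem.make_ou_model()
        times = bench.times
        c = np.exp(bench.model.population.mu)
        y = bench.simulate_cell(c, np.zeros(0), bench.xi_true, times, rng).ravel()
        sigma_huge = np.array([1e8])
        cfg_b = PFConfig(n_particles=64, kind="bootstrap", integrator="langevin", dt=0.1)
        cfg_g = PFConfig(n_particles=64, kind="guided_mdb", integrator="langevin", dt=0.1)
        u = make_auxiliary(bench.model, times, cfg_b, rng)
        vb = pf_loglik(bench.model, times, y, c, np.zeros(0), sigma_huge, u, cfg_b).value
        vg = pf_loglik(bench.model, times, y, c, np.zeros(0), sigma_huge, u, cfg_g).value
        assert np.isclose(vb, vg, rtol=1e-6)

    def test_weight_collapse_returns_minus_inf(self, zero_noise_sde_model, rng):
        model = zero_noise_sde_model
        times = np.array([1.0])
        cfg = PFConfig(n_particles=4, integrator="langevin", dt=0.1)
        u = make_auxiliary(model, times, cfg, rng)
        est = pf_loglik(model, times, np.array([1e300]), np.array([1.0]), np.zeros(0),
                        np.array([1e-3]), u, cfg)
        assert est.value == -np.inf  # a rejection signal, not an exception

    def test_ess_trace_bounds_generic_path(self, rng):
        bench = ssmem.make_ou_model()
        import dataclasses
        dyn = dataclasses.replace(bench.model.dynamics, langevin_moments_jit=None)
        model2 = dataclasses.replace(bench.model, dynamics=dyn)
        c = np.exp(bench.model.population.mu)
        y = bench.simulate_cell(c, np.zeros(0), bench.xi_true, bench.times, rng).ravel()
        cfg = PFConfig(n_particles=30, integrator="langevin", dt=0.1)
        u = make_auxiliary(model2, bench.times, cfg, rng)
        est = pf_loglik(model2, bench.times, y, c, np.zeros(0), bench.xi_true, u, cfg)
        assert np.all(est.ess_trace >= 1.0 - 1e-9)
        assert np.all(est.ess_trace <= 30.0 + 1e-9)
        assert est.n_resamples >= 0
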