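"""Evaluation toolbox: MultiESS, Wasserstein distances, particle tuning and
posterior-predictive quantile bands."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import ssmem
from ssmem import (
    PFConfig,
    multi_ess,
    posterior_visual_check,
    tune_particles,
    wasserstein1,
    wasserstein_exact_multivariate,
)
from ssmem.gibbs import PosteriorSamples


class TestMultiESS:
    def test_iid_draws_near_n(self, rng):
        n = 10**4
        m = multi_ess(rng.standard_normal((n, 3)))
        assert abs(m - n) < 0.10 * n

    def test_affine_recoordinatization_invariance(self, rng):
        n = 10**4
        X = rng.standard_normal((n, 3))
        A = np.array([[2.0, 0.3, 0.0], [0.0, 1.0, -0.5], [0.1, 0.0, 1.5]])
        m1 = multi_ess(X)
        m2 = multi_ess(X @ A.T + np.array([1.0, -2.0, 0.5]))
        assert abs(m1 - m2) / m1 < 0.05

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((500, 2))
        X[:, 1] = 3.0
        with pytest.raises(ValueError, match="column 1"):
            multi_ess(X)

    def test_duplicated_column_rejected(self, rng):
        x = rng.standard_normal(500)
        with pytest.raises(ValueError, match="degenerate|duplicated"):
            multi_ess(np.column_stack([x, x]))

    def test_more_dims_than_draws_rejected(self, rng):
        with pytest.raises(ValueError):
            multi_ess(rng.standard_normal((3, 5)))


class TestWasserstein1:
    def test_identical_zero_and_symmetry(self, rng):
        a = rng.standard_normal(100)
        assert wasserstein1(a, a) == 0.0
        b = rng.standard_normal(80)
        assert np.isclose(wasserstein1(a, b), wasserstein1(b, a))

    def test_translation_exact(self, rng):
        a = rng.standard_normal(1000)
        assert np.isclose(wasserstein1(a, a + 0.37), 0.37, rtol=1e-10)

    def test_normal_scale_pair_closed_form(self, rng):
        """W1(N(0,1), N(0,4)) = (sigma2 - sigma1) E|Z| = sqrt(2/pi); checked
        against both the sample estimate and numeric quantile integration."""
        n = 10**5
        w = wasserstein1(rng.standard_normal(n), 2.0 * rng.standard_normal(n))
        closed = np.sqrt(2.0 / np.pi)
        quadr, _ = quad(lambda u: abs(norm.ppf(u) - 2.0 * norm.ppf(u)), 1e-9, 1 - 1e-9)
        assert np.isclose(quadr, closed, rtol=1e-6)
        assert abs(w - closed) < 0.02

    def test_triangle_inequality_random_triples(self, rng):
        for _ in range(5):
            a, b, c = (rng.standard_normal(200) * s + m
                       for s, m in zip(rng.uniform(0.5, 2, 3), rng.uniform(-1, 1, 3)))
            assert wasserstein1(a, c) <= wasserstein1(a, b) + wasserstein1(b, c) + 1e-12

    def test_exact_assignment_matches_1d(self, rng):
        a, b = rng.standard_normal((2, 60))
        assert np.isclose(wasserstein_exact_multivariate(a[:, None], b[:, None]),
                          wasserstein1(a, b), rtol=1e-10)


class TestTuneParticles:
    def test_deterministic_model_needs_ladder_minimum(self, zero_noise_sde_model, rng):
        model = zero_noise_sde_model
        times = np.linspace(0.5, 2.0, 4)
        data = ssmem.Dataset([ssmem.Individual(times, np.array([4.0, 3.0, 2.5, 2.0]))])
        cfg = PFConfig(n_particles=10, integrator="langevin", dt=0.1)
        res = tune_particles(model, data, (np.array([[0.8]]), np.zeros(0), np.array([0.5])),
                             cfg, rng, mode="perturbed", n_replicates=5)
        assert res.n_particles == [10]
        assert res.variance[0] <= 1e-12

    def test_monotone_in_variance_target(self, rng):
        bench = ssmem.make_ou_model()
        data, truth = ssmem.generate_dataset(ssmem.BenchmarkSpec("ou", M=2, seed=3))
        pilot = (truth["c"], bench.kappa_true, bench.xi_true)
        cfg = PFConfig(n_particles=10, kind="bootstrap", integrator="langevin", dt=0.1)
        ladder = [5, 10, 20, 40, 80]
        loose = tune_particles(bench.model, data, pilot, cfg, np.random.default_rng(0),
                               mode="unperturbed", var_target=4.0, ladder=ladder,
                               n_replicates=15)
        tight = tune_particles(bench.model, data, pilot, cfg, np.random.default_rng(0),
                               mode="unperturbed", var_target=0.25, ladder=ladder,
                               n_replicates=15)
        assert tight.n_particles >= loose.n_particles


class TestQuantileBands:
    def _point_mass_samples(self, bench):
        pop = bench.model.population
        return PosteriorSamples(
            c=np.zeros((1, 0, pop.dim)),
            kappa=bench.kappa_true[None, :],
            xi=bench.xi_true[None, :],
            mu=pop.mu[None, :],
            omega=pop.omega[None, :, :],
        )

    def test_point_mass_zero_noise_bands_collapse(self):
        """A point-mass posterior with a deterministic simulator yields bands
        of zero width equal to the deterministic quantile curves."""
        bench = ssmem.make_ou_model()
        samples = self._point_mass_samples(bench)
        samples.omega[:] = 0.0
        times = np.linspace(1, 5, 5)

        def sim(c, kappa, xi, t, rng):
            return np.full(len(t), c[1])  # deterministic flat path

        bands = posterior_visual_check(sim, samples, times, M_cells=10, n_repeats=20, rng=1)
        for q in bands.quantiles:
            np.testing.assert_allclose(bands.lower[q], bands.upper[q])
            np.testing.assert_allclose(bands.lower[q], np.exp(samples.mu[0, 1]))

    def test_band_nesting_and_order(self):
        bench = ssmem.make_ou_model()
        samples = self._point_mass_samples(bench)
        bands = posterior_visual_check(bench.simulate_cell, samples, bench.times,
                                       M_cells=15, n_repeats=60, rng=2)
        for q in bands.quantiles:
            assert np.all(bands.lower[q] <= bands.upper[q] + 1e-12)
        # quantile order: upper envelope of q=0.05 below upper envelope of q=0.95
        assert np.all(bands.upper[0.05] <= bands.upper[0.95] + 1e-12)
        assert np.all(bands.lower[0.05] <= bands.lower[0.95] + 1e-12)

    def test_failed_repeats_are_dropped_and_counted(self):
        bench = ssmem.make_ou_model()
        samples = self._point_mass_samples(bench)
        calls = {"n": 0}

        def flaky(c, kappa, xi, t, rng):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("simulator failure")
            return np.full(len(t), 1.0)

        bands = posterior_visual_check(flaky, samples, np.linspace(1, 3, 3),
                                       M_cells=2, n_repeats=30, rng=3)
        assert bands.n_dropped > 0
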