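"""Gibbs machinery: conjugate updates, the HMC population step, prior
recovery, permutation invariance of sufficient statistics, resumability."""

import numpy as np
import pytest
from scipy import stats

import ssmem
from ssmem import InferenceConfig, NIWPrior, Priors
from ssmem.benchmarks import BenchmarkSpec
from ssmem.gibbs import EtaHMC, niw_posterior, sample_eta_conjugate


@pytest.fixture(scope="module")
def niw_prior():
    return NIWPrior(mu0=np.array([0.0, -1.0]), lambda0=0.5,
                    psi0=np.array([[0.2, 0.02], [0.02, 0.3]]), nu0=6.0)


class TestConjugateEtaStep:
    def test_single_individual_analytic_update(self, niw_prior):
        v = np.array([[0.4, -0.6]])
        post = niw_posterior(niw_prior, v)
        lam_n = niw_prior.lambda0 + 1
        assert post.lambda0 == lam_n
        assert post.nu0 == niw_prior.nu0 + 1
        np.testing.assert_allclose(
            post.mu0, (niw_prior.lambda0 * niw_prior.mu0 + v[0]) / lam_n)
        dev = (v[0] - niw_prior.mu0)[:, None]
        np.testing.assert_allclose(
            post.psi0, niw_prior.psi0 + (niw_prior.lambda0 / lam_n) * dev @ dev.T)

    def test_conjugate_consistency_many_individuals(self, niw_prior, rng):
        mu_true = np.array([0.3, -0.8])
        omega_true = np.array([[0.04, 0.01], [0.01, 0.09]])
        V = rng.multivariate_normal(mu_true, omega_true, size=1000)
        draws_mu = np.stack([sample_eta_conjugate(niw_prior, V, rng)[0] for _ in range(400)])
        post_sd = draws_mu.std(axis=0)
        assert np.all(np.abs(draws_mu.mean(axis=0) - mu_true) < 3 * post_sd + 0.02)
        omegas = np.stack([sample_eta_conjugate(niw_prior, V, rng)[1] for _ in range(400)])
        np.testing.assert_allclose(omegas.mean(axis=0), omega_true, atol=0.02)

    def test_diag_family_zero_off_diagonal(self, niw_prior, rng):
        V = rng.standard_normal((50, 2))
        mu, omega = sample_eta_conjugate(niw_prior, V, rng, family="lognormal_diag")
        assert omega[0, 1] == 0.0 and omega[1, 0] == 0.0
        assert omega[0, 0] > 0 and omega[1, 1] > 0

    def test_permutation_invariance_exact(self, niw_prior, rng):
        """The eta draw depends on individuals only through permutation-
        invariant sufficient statistics: permuting rows gives bit-identical
        draws under the same random state (up to float summation order)."""
        V = rng.standard_normal((7, 2))
        perm = rng.permutation(7)
        mu1, om1 = sample_eta_conjugate(niw_prior, V, np.random.default_rng(99))
        mu2, om2 = sample_eta_conjugate(niw_prior, V[perm], np.random.default_rng(99))
        np.testing.assert_allclose(mu1, mu2, rtol=1e-8)
        np.testing.assert_allclose(om1, om2, rtol=1e-8)


class TestEtaHMC:
    def test_gradient_matches_finite_differences(self, niw_prior, rng):
        hmc = EtaHMC(niw_prior)
        V = rng.standard_normal((12, 2)) * 0.3
        phi = rng.standard_normal(5) * 0.3
        lp, grad = hmc._logp_grad(phi, V)
        eps = 1e-6
        for k in range(5):
            dphi = np.zeros(5)
            dphi[k] = eps
            lp_p = hmc._logp_grad(phi + dphi, V)[0]
            lp_m = hmc._logp_grad(phi - dphi, V)[0]
            fd = (lp_p - lp_m) / (2 * eps)
            assert np.isclose(grad[k], fd, rtol=1e-4, atol=1e-6), f"coordinate {k}"

    def test_agrees_with_conjugate_sampler(self, niw_prior, rng):
        """HMC and the exact NIW draw target the same full conditional:
        per-coordinate Wasserstein distance small relative to the posterior SD."""
        V = rng.multivariate_normal([0.2, -0.5], np.diag([0.05, 0.08]), size=40)
        conj = np.stack([
            np.concatenate([*_pair(sample_eta_conjugate(niw_prior, V, rng))])
            for _ in range(10000)
        ])
        hmc = EtaHMC(niw_prior, n_leapfrog=10)
        mu, omega = sample_eta_conjugate(niw_prior, V, rng)
        draws = []
        for it in range(12000):
            mu, omega = hmc.sample(V, mu, omega, rng)
            if it >= 2000:
                draws.append(np.concatenate([*_pair((mu, omega))]))
        hmc_draws = np.stack(draws)
        for k in range(conj.shape[1]):
            sd = conj[:, k].std()
            w = ssmem.wasserstein1(conj[:, k], hmc_draws[:, k])
            assert w < 0.05 * sd, f"coordinate {k}: W1/SD = {w / sd:.3f}"


def _pair(mu_omega):
    mu, omega = mu_omega
    return mu, np.sqrt(np.diag(omega))


class TestEngine:
    def test_prior_recovery_with_no_individuals(self):
        """M = 0, unperturbed: step 2 reduces to a random walk on the prior
        pi(kappa, xi); the chain reproduces the prior moments."""
        bench = ssmem.make_schlogl_model()
        data = ssmem.Dataset([])
        cfg = InferenceConfig(n_iterations=6000, mode="unperturbed", burn_in=0.3,
                              pf=bench.pf_default)
        samples, _ = ssmem.run_inference(bench.model, data, cfg, 7, priors=bench.priors)
        log_kappa = np.log(samples.kappa)
        pr = bench.priors
        for k in range(2):
            assert abs(log_kappa[:, k].mean() - pr.kappa_mean[k]) < 0.15
            assert abs(log_kappa[:, k].std() - pr.kappa_sd[k]) < 0.15
        assert abs(np.log(samples.xi).mean() - pr.xi_mean[0]) < 0.15

    def test_resumed_run_bit_identical(self):
        bench = ssmem.make_ou_model()
        data, _ = ssmem.generate_dataset(BenchmarkSpec("ou", M=3, seed=5))
        cfg = InferenceConfig(n_iterations=40, mode="unperturbed", burn_in=0.0,
                              eta_kind="conjugate_niw")

        def kal(times, y, c, kappa, xi):
            ou = ssmem.OUModel(c[0], c[1], c[2], xi[0])
            return ssmem.kalman_loglik(ou, times, y, x0_law="fixed", x0=c[1])

        _, state_a = ssmem.run_inference(bench.model, data, cfg, 11, priors=bench.priors,
                                         exact_loglik=kal)
        _, half = ssmem.run_inference(bench.model, data, cfg, 11, priors=bench.priors,
                                      exact_loglik=kal, n_iterations=20)
        _, state_b = ssmem.run_inference(bench.model, data, cfg, 11, priors=bench.priors,
                                         exact_loglik=kal, resume=half, n_iterations=20)
        assert np.array_equal(state_a.theta, state_b.theta)
        assert np.array_equal(state_a.mu, state_b.mu)
        assert np.array_equal(state_a.omega, state_b.omega)
        assert np.array_equal(state_a.xi_t, state_b.xi_t)

    def test_individual_acceptance_rates_reported(self):
        bench = ssmem.make_ou_model()
        data, _ = ssmem.generate_dataset(BenchmarkSpec("ou", M=3, seed=6))
        cfg = InferenceConfig(n_iterations=60, mode="perturbed",
                              pf=ssmem.PFConfig(n_particles=20, integrator="langevin", dt=0.1,
                                                kind="guided_mdb", rho=0.9))
        samples, _ = ssmem.run_inference(bench.model, data, cfg, 13, priors=bench.priors)
        rates = samples.accept_rates["individual"]
        assert len(rates) == 3
        assert all(0.0 <= r <= 1.0 for r in rates)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            InferenceConfig(mode="sideways")
        with pytest.raises(ValueError):
            InferenceConfig(mode="perturbed", delta=0.0)
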