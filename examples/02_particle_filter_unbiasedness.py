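"""Verify the particle filter against the exact Kalman likelihood.

On the Ornstein-Uhlenbeck benchmark the likelihood of the (Euler-
discretised) state-space model is available in closed form, so the
pseudo-marginal cornerstone — E[exp(estimate)] equals the true likelihood —
can be checked directly.  Also shows the variance advantage of the guided
(modified diffusion bridge) filter over the bootstrap filter.
"""
import numpy as np

import ssmem

rng = np.random.default_rng(7)
bench = ssmem.make_ou_model()
c = np.exp(bench.model.population.mu)          # (theta1, theta2, theta3)
sigma = bench.xi_true
y = bench.simulate_cell(c, np.zeros(0), sigma, bench.times, rng).ravel()

ou = ssmem.OUModel(c[0], c[1], c[2], sigma[0])
L = ssmem.kalman_loglik_euler(ou, bench.times, y, dt=0.1, x0=c[1])
print(f"exact log-likelihood of the discretised model: {L:.3f}")

for kind in ("bootstrap", "guided_mdb"):
    cfg = ssmem.PFConfig(n_particles=100, kind=kind, integrator="langevin", dt=0.1)
    vals = []
    for _ in range(500):
        u = ssmem.make_auxiliary(bench.model, bench.times, cfg, rng)
        vals.append(ssmem.pf_loglik(bench.model, bench.times, y, c, np.zeros(0),
                                    sigma, u, cfg).value)
    vals = np.array(vals)
    ratio = np.exp(vals - L)
    print(f"{kind:11s}: mean ratio = {ratio.mean():.3f} +- {ratio.std()/np.sqrt(500):.3f}  "
          f"var(loglik) = {vals.var():.4f}")
print("Both ratios are 1 within Monte Carlo error (unbiasedness); the guided")
print("filter achieves it with a far smaller estimator variance at equal N.")
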