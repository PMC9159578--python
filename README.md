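# ssmem

Bayesian inference for **state-space mixed-effects models** (SSMEMs) of
single-cell stochastic dynamics.

Time-lapse microscopy follows a biochemical process — gene expression, a
signalling pathway — in many cells at once.  Two noise sources shape such
data: *intrinsic* noise from the randomness of chemical reactions at low
molecule numbers, and *extrinsic* noise from parameters that differ between
cells.  `ssmem` infers both from multi-cell time series: per cell *i* a
latent Markov process **x**(t) (reaction network or SDE) with
cell-individual rates **c**⁽ⁱ⁾ and shared parameters **κ** is observed as
y = g(**x**, t) + ε, ε ~ N(0, σ²), and the cell-individual rates follow a
log-normal population law **c**⁽ⁱ⁾ ~ LN(**μ**, **Ω**).  The target is the
hierarchical posterior

    π(c, κ, η, ξ | y) ∝ π(c, κ, η, ξ) ∏ᵢ π(y⁽ⁱ⁾ | c⁽ⁱ⁾, κ, ξ),

with η = (μ, Ω) the population parameters and ξ the error scales.

The engine combines:

* **simulators** for intrinsic noise — exact SSA and Extrande (thinning,
  for time-varying rates), approximate tau-leap and chemical Langevin;
* **particle filters** providing non-negative unbiased likelihood
  estimates — bootstrap and guided (modified diffusion bridge) variants,
  with correlated auxiliary numbers (u' = ρu + √(1−ρ²)ζ) for cheap
  pseudo-marginal moves;
* **adaptive proposals** — AM, AM with global scaling, robust AM (RAM);
* two **Metropolis-within-Gibbs samplers**: the classic three-step sampler
  (per-cell blocks / cell-constant block / population block) and the
  default *perturbed* sampler, which lets cell-constant parameters vary
  weakly between cells (κ⁽ⁱ⁾ ~ N(κ_pop, δ²I) on log scale) so the
  expensive cell-constant step — whose summed likelihood-estimate variance
  grows with the number of cells — disappears;
* a **Kalman oracle** for the linear-Gaussian Ornstein-Uhlenbeck benchmark,
  giving exact likelihoods and a gold-standard posterior that every
  stochastic component is validated against;
* an **evaluation toolbox**: particle-count tuning, multivariate ESS,
  Wasserstein distances, posterior visual checks.

Three synthetic benchmarks (a circadian-clock gene-expression model, the
bistable Schlögl model, and the OU model) generate all test data; see
`docs/methods.md` for the model details and every default.

## A worked example

```python
import numpy as np
import ssmem
from ssmem.benchmarks import BenchmarkSpec

bench = ssmem.make_schlogl_model()
data, truth = ssmem.generate_dataset(BenchmarkSpec("schlogl", M=12, seed=41))

cfg = ssmem.InferenceConfig(n_iterations=2500, mode="perturbed", burn_in=0.5,
                            pf=bench.pf_default)  # Langevin + guided + rho=0.999
samples, _ = ssmem.run_inference(bench.model, data, cfg, 700, priors=bench.priors)
```

Running `python examples/04_schlogl_guided_inference.py` (which does the
above and prints a summary) gives:

```
dataset: 12 cells, 3 of them switch state at least once
parameter        truth  post mean                95% CI
mu (log c1)     -3.442     -3.634   [  -3.917,   -3.402]
tau               0.15     0.1809   [ 0.09205,   0.3367]
c2              0.0006  0.0005744   [0.0004896, 0.0006923]
c3                   9      9.866   [   8.729,    11.15]
sigma                2      1.648   [   1.356,    2.024]
```

Every 95% credible interval covers the generating value: from noisy counts
of a bistable network the sampler recovers the population law of the
cell-varying synthesis rate (μ, τ), the shared rates (c₂, c₃) and the
measurement noise — using ~10 particles per cell, which is what the
guided filter plus correlated auxiliary numbers buy.

The other scripts in `examples/` walk through the simulators, filter
unbiasedness against the Kalman oracle, the three-way OU sampler
comparison, and posterior visual checks.  A thin CLI mirrors the library
(`ssmem generate | simulate | tune | infer | diagnose | check`); run
configurations are TOML files (`ssmem infer --config run.toml`), chains are
written as delimited text plus a binary container with a checksummed
manifest.

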