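# Methods

## The model class

`ssmem` performs Bayesian inference for state-space mixed-effects models
(SSMEMs) of single-cell dynamics.  Per cell *i* = 1…M a latent Markov
process **x**(t) — a chemical reaction network driven by intrinsic noise, or
an SDE — evolves under cell-individual rate constants **c**⁽ⁱ⁾, shared
cell-constant parameters **κ**, and is observed at times t₁…t_{nᵢ} through

    y_l = g(x(t_l), t_l) + ε_l,    ε_l ~ N(0, diag(σ²)),

with error scales **ξ** = σ.  Extrinsic (between-cell) noise is modelled
hierarchically: **c**⁽ⁱ⁾ ~ LN(**μ**, **Ω**), with population parameters
**η** = (**μ**, **Ω**).  The target is the joint posterior

    π(c, κ, η, ξ | y) ∝ π(c, κ, η, ξ) ∏ᵢ π(y⁽ⁱ⁾ | c⁽ⁱ⁾, κ, ξ).

All positive parameters are stored and proposed on the log scale; the
population law is Gaussian on that scale, so conjugate machinery applies
there and proposals are unconstrained.  Cell-varying initial states are
encoded as extra coordinates of **c** (the initial-state rule may be any
function of **c**), which keeps one inference machinery for all unknowns.

## Simulators for intrinsic noise

Four integrators are provided, and the engine never switches between them
on its own (tau-leap/Langevin are opt-in where the leap conditions are
deemed acceptable):

* **SSA** (Gillespie direct): exact for time-invariant propensities.
* **Extrande** (thinning): exact with time-varying propensities.  The
  upper bound B for a lookahead window (here: the current inter-observation
  interval) is, by default, the maximum of the total propensity on a small
  time grid at the current state, inflated by a safety factor (default
  1.5), and is recomputed after every accepted event.  Every candidate
  event checks the bound; a violation is a hard error reporting the time
  and deficit, so a too-small numeric bound can never silently bias a
  simulation.  A user-supplied bound function or constant is accepted.
* **Tau-leap**, fixed step: x ← x + S·Poisson(h dt).  The last sub-step of
  each interval is truncated so output times are hit exactly.  Species
  driven negative have their propensity contributions clamped to zero; the
  stand-alone simulator clips states at zero, while inside a particle
  filter negative particles instead receive zero weight — this preserves
  the unbiasedness bookkeeping without rejection loops.
* **Chemical Langevin** (Euler–Maruyama): x ← x + S h dt + S√(h dt)·z.
  States are real-valued and may go negative; propensity evaluations clamp
  the state at zero (a reflecting-drift convention).

Random-number accounting is fixed per filter configuration: tau-leap
consumes Poisson counts derived from standard normals via the inverse CDF
of their Φ-transform, Langevin consumes standard normals directly.  This
fixed layout is what makes the correlated pseudo-marginal scheme possible
for these two integrators; SSA/Extrande draw a variable number of event
times and therefore always use fresh randomness (ρ forced to 0).

## Particle filters

The per-cell likelihood π(y⁽ⁱ⁾|c⁽ⁱ⁾,κ,ξ) is intractable; a particle filter
provides a non-negative unbiased estimate, which is all a pseudo-marginal
sampler needs to target the exact posterior.

* **Bootstrap filter**: particles propagate blindly with the model
  simulator and are weighted by the observation density.  Weight
  arithmetic is in log space throughout (log-sum-exp).
* **Guided filter (modified diffusion bridge)**: for Langevin dynamics
  with a linear-Gaussian observation y = P x + ε.  With Δ the time to the
  next observation, a(x) the drift and Γ(x) the diffusion covariance, each
  Euler sub-step of length dt proposes from the one-step-conditioned
  Gaussian

      ψ = P Γ Pᵀ Δ + Σ_ε,
      μ = x + [a + Γ Pᵀ ψ⁻¹ (y − P(x + aΔ))] dt,
      Σ = (Γ − Γ Pᵀ ψ⁻¹ P Γ dt) dt,

  i.e. the conditional law of the Euler increment given the observation
  under the locally linear Gaussian approximation.  The importance weight
  accumulates log N(x'; x + a dt, Γ dt) − log N(x'; μ, Σ) per sub-step, so
  the estimator stays unbiased.  As σ → ∞ the proposal decays to the blind
  Euler step and the weights to bootstrap weights (tested).  Guided
  support for jump integrators is not provided; the guided path is exactly
  the configuration used for the bistable benchmark.
* **Resampling**: systematic, triggered when ESS < 0.5·N (configurable),
  never after the final observation.  When ρ > 0 particles are sorted by
  state (first coordinate, then lexicographic) before resampling, and the
  resampling uniform is itself derived from a dedicated auxiliary normal —
  both are needed for the correlation of successive likelihood estimates
  to survive resampling.
* **Correlated estimates**: between MCMC iterations the auxiliary normals
  refresh as u' = ρu + √(1−ρ²)ζ, preserving the N(0,1) marginal.  At
  ρ = 0.999 successive log-likelihood estimates at fixed parameters
  correlate at ≳0.98 on the OU benchmark, which is what lets ~10 particles
  per cell suffice.
* A weight collapse (all particles at −∞) returns −∞ — a Metropolis
  rejection signal, never an exception.

Scalar-state Langevin filters (both kinds) and jump-integrator bootstrap
filters with a scalar linear observation run as compiled (numba) kernels;
a test pins the compiled and the reference numpy paths to identical
values on shared auxiliary numbers.

## Samplers

The posterior is explored by Metropolis-within-Gibbs:

1. **Individual blocks.**  For each cell, propose (log c⁽ⁱ⁾)' (jointly
   with the per-cell κ⁽ⁱ⁾, ξ⁽ⁱ⁾ copies in perturbed mode) with that
   cell's adaptive proposal, refresh u⁽ⁱ⁾ with ρ, and accept with the
   pseudo-marginal ratio.  Stored log-likelihood estimates always
   correspond to the stored (parameters, u) pair.
2. **Cell-constant block** (unperturbed mode only).  Propose (κ, ξ)'
   jointly, re-estimate all M likelihoods with refreshed correlated
   auxiliary numbers, accept on the product.  The variance of the summed
   estimate grows with M, which is what makes this step expensive — the
   measured tuned particle counts (below) quantify it.
3. **Population block.**  (μ, Ω) has a tractable full conditional given
   log c: a Normal-Inverse-Wishart draw (exact), or one Hamiltonian Monte
   Carlo transition for non-conjugate settings.  The HMC step runs
   leapfrog (default 10 steps) on (μ, log diag L, strict lower triangle of
   L) with Ω = LLᵀ, includes the Cholesky-transform Jacobian, uses
   analytic gradients (finite-difference checked), targets 0.8 acceptance
   by dual averaging, and rejects on energy divergences.  HMC and the
   conjugate draw agree to within 0.05 posterior SD in 1-d Wasserstein
   distance on the same problem (tested).

**Perturbed mode (default).**  Cell-constant parameters are perturbed to
vary weakly between cells: κ⁽ⁱ⁾ ~ N(κ_pop, δ²I) on the log scale (likewise
ξ), with δ = 0.1 by default (config-exposed).  The per-cell copies join
step 1, the population locations get closed-form Gaussian updates in step
3, and step 2 disappears.  The observable cost: the error-scale location's
posterior can be slightly wider than in the unperturbed sampler.  The
observable benefit: the per-cell likelihood variance, not the summed one,
sets the particle count, so the tuned N stays flat as M grows.

Adaptive proposals: AM, AM with global scaling, and robust AM (RAM;
default, target acceptance 0.234, γ_n = n^(−0.66), σ₀ = 0.1).  Adaptation
is diminishing and continues for the whole run by default (an optional
freeze iteration is exposed).  Each individual block has its own proposal
state; step 2 has its own.

Initialisation draws c⁽ⁱ⁾ from the prior-predictive at the prior-mean η
(re-drawing a cell up to 100 times if its initial likelihood estimate is
−∞); user-supplied starts are accepted.  Each cell owns a spawned child
RNG stream, so runs are reproducible and resumable bit-identically from a
checkpointed chain state (tested).  Multiple chains are independent
`run_inference` calls with distinct seeds.

## The Kalman oracle

The OU model dX = θ₁(θ₂−X)dt + θ₃dW with y = x + ε is linear-Gaussian;
`kalman_loglik` evaluates the exact likelihood by scalar prediction/update
recursions (verified against a brute-force joint-Gaussian density to
1e−10).  `exact_gibbs_ou` runs the same Gibbs loops with the Kalman
likelihood replacing every particle-filter estimate — the gold standard
posterior for validating both pseudo-marginal samplers.

One point needs care: an Euler-discretised filter unbiasedly estimates the
likelihood of the *discretised* state-space model, which differs from the
exact OU likelihood by O(dt).  `kalman_loglik_euler` evaluates the
discretised model's likelihood in closed form and is the matched oracle
for unbiasedness checks at finite dt (at the default dt the two oracles
differ by well under 2%, which the posterior comparisons absorb).

## Benchmarks (the synthetic study conditions)

True parameter values below are package defaults chosen once to reproduce
the qualitative regimes (strong intrinsic noise at low copy numbers;
stochastic bistability; well-conditioned OU recovery); they are exposed by
the factories and used by the recovery scoring.

* **Circadian gene expression** — species (mRNA, protein); reactions:
  transcription ∅→mRNA at c₁(1 + 0.5 sin 2πt/24) (period 24 h), mRNA decay
  c₂, translation c₃, protein decay c₄; true rates (1.0, 0.3, 1.0, 0.2)/h,
  x₀ = (0,0), so mean protein ≈ 17 and mRNA ≈ 3 — low copy numbers.  All
  four rates are cell-varying, log-normal with τ = (0.20, 0.15, 0.20,
  0.15) and corr(c₃,c₄) = 0.5 (synthesis/degradation co-vary).  Protein
  observed with σ = 2.0 at 25 points over 72 h; M = 40 cells by default.
  Data generation and filtering use Extrande (the sine-modulated rate
  rules out plain SSA).
* **Schlögl** — one species; 2X→3X (c₁), 3X→2X (c₂), ∅→X (c₃), X→∅ (c₄
  known).  Combinatorial mass-action propensities by default (x(x−1)/2,
  x(x−1)(x−2)/6); the power convention (x²/2, x³/6) is selectable.  True
  values c₁ = 0.032 (cell-varying, τ = 0.15), κ = (6·10⁻⁴, 9.0),
  c₄ = 0.73 put the deterministic fixed points near 20/90 (unstable ≈ 50),
  so cells switch stochastically within the 40-unit horizon (40
  observations, σ = 2, x₀ = 20).  Data are generated with the exact SSA;
  inference uses Langevin (dt = 0.2) + guided bridge filter + ρ = 0.999 —
  the simulate-exact / infer-approximate structure is deliberate and
  preserved.
* **OU** — (θ₁, θ₂, θ₃) cell-varying log-normal, true medians (0.8, 5.0,
  1.0), τ = (0.15, 0.10, 0.15) diagonal; σ = 0.3; 20 observations over 10
  time units; each cell starts at its own θ₂.  Data generation uses the
  exact discrete transition; the filter uses the Euler path (dt 0.1, or
  0.05 inside the posterior-exactness comparison).

Priors are weakly informative and deliberately off-centre from the truth:
NIW hyperpriors on (μ, Ω) (for OU, λ₀ = 1, ν₀ = 10, prior-mean τ ≈ 0.2 —
chosen so the small-M hierarchy is well-conditioned and sampler
comparisons are not drowned in population-block wander), log-normal priors
on κ and σ with SDs 0.5–0.7.

What the generator emulates: intrinsic reaction noise, log-normal
extrinsic parameter variation, additive Gaussian measurement error on a
(linear or ratio) observable, a common observation grid.  What it does not:
cell growth/division and lineage, segmentation/tracking artefacts,
non-Gaussian or multiplicative measurement error, missing observations,
between-cell correlation beyond the population law.  Passing the recovery
suites therefore demonstrates the inference machinery, not robustness to
those real-data features.

## Evaluation toolbox

* **Particle tuning**: at a pilot parameter point, walk a geometric ladder
  (10, 15, 23, …) and pick the smallest N whose log-likelihood estimator
  variance over 25 replicate filter runs is ≤ 2.0 (the usual
  pseudo-marginal working rule).  Perturbed mode tunes each cell's own
  variance; unperturbed mode tunes the variance of the summed
  log-likelihood.
* **MultiESS**: n·(det Λ̂/det Σ̂)^{1/p} with Λ̂ the sample covariance and Σ̂
  the multivariate batch-means long-run covariance (batch size ⌊√n⌋);
  the first 20% of a chain is discarded before evaluation.
* **Wasserstein**: 1-d first-order distances per parameter (scipy backend;
  cross-checked in tests against closed forms, quantile integration and an
  exact small-n multivariate assignment solver).
* **Posterior visual check**: each repeat draws one saved posterior sample
  (η, κ, ξ), simulates a full population of M cells through the exact
  simulator and the error model, records the 0.05/0.5/0.95 quantiles per
  time point; bands are the 95% envelopes across repeats (default 500
  repeats, config-exposed; failed repeats are dropped and counted).

## Desk-scale test conditions

The acceptance suite validates the engine end-to-end on one CPU; problem
sizes are the package's own desk-scale choices, fixed before the suite was
frozen:

* filter unbiasedness: 500 replicate filters, N = 100, both kinds, ρ ∈ {0,
  0.999};
* OU posterior exactness: M = 5 cells × 20 observations, 2·10⁴ iterations
  per sampler (perturbed, unperturbed, Kalman-exact), guided filter
  N = 50, dt = 0.05, ρ = 0.999; distances in units of the gold-standard
  posterior SD;
* circadian recovery: M = 10 cells, 25 points over 72 h, Extrande
  bootstrap filter N = 40, 5·10³ iterations, 3 seeded replicates;
* Schlögl recovery: M = 12 cells, 2.5·10³ iterations, Langevin + guided +
  ρ = 0.999, N = 10; posterior-predictive switching via 150 simulated
  cells;
* scalability trend: tuned particle counts on Schlögl data at M ∈ {20,
  40, 80} for both sampler modes.

## Known limitations

* Guided proposals are restricted to Langevin dynamics with linear-
  Gaussian observations; jump-process guided filters are not implemented.
* The Langevin filter targets the Euler-discretised model; dt is a
  bias/cost dial the user owns.
* tau-leap uses a fixed step; no adaptive step selection, no hybrid
  jump/diffusion simulators.
* The HMC population step covers the log-normal family (full or diagonal
  covariance) with an NIW prior; other population laws would need their
  own gradient code.
* Per-cell updates are sequential; no parallelism across cells.
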