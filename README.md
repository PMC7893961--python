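# movegp

Hierarchical non-stationary Gaussian-process models for animal movement
telemetry.

## The problem

GPS collars produce long, high-frequency trajectories whose statistical
character changes continuously: animals range widely at some hours and
encamp at others, migrate seasonally along routes that themselves drift
over years. Classical continuous-time movement models — above all the
Ornstein–Uhlenbeck (OU) process — assume fixed parameters, and
discrete-state alternatives (hidden Markov models) force behaviour into a
predeclared number of modes.

`movegp` models movement as a 2-D Gaussian process whose kernel parameters
are *functions of time*, each governed by its own lower-level GP. For
positions (or velocities) `x(t) = f(t) + ε`, `ε ~ N(0, σ_m²)`:

    f(t) ~ GP(m(t), K_NS(t, t'))

    K_NS(t,t') = sqrt( 2 σ²(t) σ²(t') L(t) L(t') / (L(t)² + L(t')²) )
                 · exp( −sqrt( 2 (t−t')² / (L(t)² + L(t')²) ) )

a non-stationary Matérn 1/2 kernel whose amplitude σ(t) and correlation
lengthscale L(t) correspond to the parameters of a time-varying OU process
via `L = 1/ν`, `σ² = η²/(2ν)`. The latents are themselves GPs,

    log σ(t) ~ GP(μ_σ, K_σ),   log L(t) ~ GP(μ_L, K_L),   m(t) ~ GP(0, K_m),

with kernels chosen to encode structure: an exactly periodic kernel for
daily rhythms (P = 24 h), or a periodic × squared-exponential product for
an annual cycle drifting over years. Any subset of {σ, L, m} may be
dynamic; with all constant the model is a plain OU walker.

Inference is by the Metropolis-adjusted Langevin algorithm (MALA) on
whitened coordinates (`f = μ + chol(K)·w`, `w ~ N(0, I)`), with
Robbins–Monro step-size tuning and a diagonal preconditioner adapted
during burn-in, exact hand-derived gradients of the log posterior, and
optional Adam MAP optimization for the optimize-then-sample workflow.
Long trajectories are split into segments treated as conditionally
independent local GPs sharing the latents, reducing the O(n³) likelihood
to a sum of cheap terms. Convergence is assessed with the Gelman–Rubin
PSRF and autocorrelation-based effective sample sizes; fitted models are
validated with step-length / turn-angle posterior predictive checks.

Who it is for: movement ecologists with tabular telemetry (`id,time,x,y`)
who want continuous behavioural states with full uncertainty, and
methodologists wanting a small, dependency-light reference implementation
of hierarchical non-stationary GP regression.

## Worked example

```python
from movegp import SamplerConfig
from movegp.experiments import run_daily_activity_experiment

res = run_daily_activity_experiment(
    seed=7, n_days=4,
    sampler=SamplerConfig(n_steps=2500, n_burnin=1000, thin=5, n_chains=4,
                          initial_step_size=0.05),
)
print(f"max PSRF: {res.max_psrf:.3f}")
print(f"nu posterior mean: {res.extras['nu_post_mean']:.2f} (truth 12)")
print(f"amplitude band coverage: {res.extras['coverage']:.2f}")
```

This simulates 4 days of 10-minute fixes from an OU walker (ν = 12 h⁻¹,
mean at the origin) whose noise amplitude follows a smoothed daily
sawtooth — low overnight, rising from 5 am, dropping sharply at 5 pm —
then fits the hierarchy with a 24-h periodic kernel on log σ(t) at 40
support points and 4 adaptive-MALA chains. Running it prints:

```
max PSRF: 1.011
nu posterior mean: 13.31 (truth 12)
amplitude band coverage: 0.97
```

PSRF ≈ 1 says the four chains agree; the posterior mean of the
mean-reversion rate sits within ~11% of the simulating value on these 4
days of data (the 10-day run used by the acceptance script gets within a
few percent); and the 95% credible band for σ(t) covers the true daily
activity profile at 97% of the support points. The scripts in `examples/` walk through each
capability (kernels, generators, fitting, migration means, step/turn
checks) in the same style; the command-line interface (`movegp
simulate-activity | simulate-migration | fit | diagnose | ppc`) wraps the
same functions for shell use.

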