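# Methods

## Model

Movement is observed as `x(t) = f(t) + ε` with iid Gaussian measurement
error `ε ~ N(0, σ_m²)`. The latent path `f` is a 2-D Gaussian process;
each coordinate is modelled as a univariate GP and the two share the
covariance function and measurement noise while keeping separate means.
(Explicitly correlated multi-output GPs are out of scope; for telemetry
the difference is negligible because the shared time-varying kernel
already couples the coordinates' variability.)

The covariance is the non-stationary Matérn 1/2 kernel

    K_NS(t,t') = sqrt( 2 σ²(t) σ²(t') L(t) L(t') / (L(t)²+L(t')²) )
                 · exp( −sqrt( 2 (t−t')² / (L(t)²+L(t')²) ) ),

whose diagonal is σ(t)² and which reduces entrywise to the stationary
exponential kernel `σ_k exp(−|t−t'|/L)` under constant parameters with
`σ_k = σ²`. We adopt the convention that the stationary amplitude
parameter is the zero-lag *variance*; this makes the stationary and
non-stationary forms consistent (the non-stationary diagonal is
unambiguously σ(t)²) and gives the OU correspondence

    L(t) = 1/ν(t),    σ(t)² = η(t)²/(2ν(t))

for the time-varying OU SDE `dx = −ν(t)(x − m(t)) dt + η(t) dW`.

Each behavioural latent is a lower-level GP represented at `m ≪ n`
support points placed evenly over its domain (40 points over the 24-h
circle for daily rhythms, i.e. 0.6-h spacing; ~30 per year for annual
latents), with values elsewhere obtained by noiseless conditional-mean
interpolation from the support values (subset-of-regressors style).
log σ(t) and log L(t) carry constant prior means μ_σ, μ_L and an
exponential transform; the mean function m(t) is a zero-mean GP per
coordinate. Lower-level kernels implemented: exponential, exactly
periodic `a exp(−2 sin²(π|Δ|/P)/l²)`, and the quasi-periodic product of
the periodic kernel with a squared-exponential envelope `exp(−Δ²/2λ²)`.
Periods (24 h, 1 yr) and the envelope timescale (5 yr) are fixed
structural choices, never sampled; amplitudes and periodic lengthscales
can be sampled or fixed per model. When a movement parameter is static it
is a positive constant sampled on the log scale. When several latents
describe one process (the two coordinates of a migration mean) they can
share their kernel hyperparameters through a named hyper-group; the
migration preset does this, which also removes the amplitude funnel a
near-zero coordinate would otherwise create.

## Posterior and gradients

Sampling operates on whitened coordinates: each latent's support values
are `μ + chol(K_ss + jitter)·w` with `w ~ N(0, I)` a priori, which
decorrelates the posterior. The joint unnormalized log posterior is the
sum of per-segment Gaussian data log-likelihoods (segments and
individuals are conditionally independent given the latents), standard
normal log-densities of the whitened vectors, and independent
`N(0, 2²)` priors on every sampled scalar — prior means, log constants,
log kernel hyperparameters, log σ_m. The sd-2 default is weakly
informative on log scales (±2 sd spans a factor of ~55) and is
configurable per entry.

Gradients are exact and hand-derived: `d logN/dΣ = ½Σ_c α_c α_cᵀ − Σ⁻¹`
with `α_c = Σ⁻¹(x_c − m_c)`, chained through the closed-form partials of
K_NS with respect to the pointwise σ(t), L(t), through the conditional
interpolation (a fixed linear map given hyperparameters), the exponential
transform, and the whitening. Kernel-hyperparameter directions use the
forward-mode Cholesky differential `dC = C Φ(C⁻¹ dK C⁻ᵀ)` (Φ = lower
triangle, halved diagonal); with at most a handful of hyperparameters the
forward mode costs a few m×m products per direction. Tests verify the
gradient against central finite differences to <1e−4 relative error on
random small instances.

Numerical choices: the data covariance gets a fixed absolute diagonal
jitter of 1e−8 in addition to σ_m²; support-kernel matrices get a
relative jitter of 1e−6 × mean diagonal; the generic `add_jitter` helper
doubles the jitter up to 3 retries on Cholesky failure. Latent evaluation
outside the support range (plus a 10% margin) logs a warning but is still
computed. Time-difference matrices and kernel feature matrices (sin²
terms) are precomputed once per fit, so each MALA step costs one Cholesky
per segment plus small interpolation products.

## Sampling

Adaptive MALA: proposals `x' = x + (ε²/2) D ∇logπ(x) + ε √D ξ` with a
Metropolis–Hastings correction for the asymmetric proposal, where D is a
proposal metric (identity, diagonal, or dense). During burn-in only, the
log step size follows a Robbins–Monro schedule (gain k^−0.6) toward the
MALA-optimal acceptance rate 0.574. If no metric is supplied, D is
re-estimated from the most recent burn-in window at 25/50/75% of burn-in
(dense with diagonal shrinkage when the window holds enough draws,
diagonal otherwise; the step-size schedule restarts at each refresh so ε
can re-tune). Everything is frozen after burn-in; burn-in draws are
discarded and the rest thinned. Chains get independent seeds spawned
from the master seed; identical configurations are bit-identical. Chains
whose acceptance falls below 1% over a 200-step window trigger a logged
warning.

Both experiment presets use the optimize-then-sample workflow: Adam
(learning rate 0.05) finds a MAP, the static parameters are frozen at
their optimized values θ̂, and the chains sample the rest — jointly
sampling kernel hyperparameters creates an amplitude–latent funnel that
mixes far too slowly to be worth it at desk-scale chain lengths, the
same trade observed on large real datasets. The daily-activity preset
freezes the periodic-kernel hyperparameters (a, l) and samples the
whitened amplitude vector, μ_σ and the constant log L; the migration
preset optimizes in stages (mean-function latents first — the joint MAP
from a flat mean otherwise falls into a degenerate basin where the
movement amplitude absorbs the whole migration — then everything, taking
the better of the staged and direct optima), freezes all static
parameters including the constant σ and L, and samples the
mean-function latents, whose posterior given θ̂ is exactly Gaussian.

A Laplace proposal metric is computed at the MAP (Hessian of −log
posterior by central differences of the exact gradient, eigenvalues
floored at 0.1 — posterior curvature cannot fall much below the prior's —
and inverted) and shared by all chains, which start overdispersed around
the MAP. The whitened posterior is severely anisotropic (condition
numbers ~10⁴), so this metric is what makes thousand-step chains mix: on
the daily-activity posterior it takes the worst-coordinate PSRF from ~3
to ~1.00 at equal cost. `optimize_hyperparameters` can also restrict
updates to named blocks.

Diagnostics: the Gelman–Rubin PSRF per parameter,
`sqrt(((n−1)/n · W + B/n)/W)` with W the mean within-chain variance and
B/n the sample variance of the chain means; and autocorrelation-based ESS
(FFT autocovariances pooled over chains, Geyer initial-positive-sequence
truncation, capped at the total draw count). Experiment summaries take
the max PSRF over both the sampled coordinates and the *transformed*
latent values at the support points, so a reparameterization cannot hide
poor mixing. The test suite cross-checks both statistics against arviz.

## Segmentation

Long trajectories are split into consecutive segments of j points
(keep-short-tail by default; discarding data is worse than one small
segment). The local-GP product is accurate when each segment spans many
correlation lengthscales; tests verify <1% relative likelihood error at
spans ≥ 50 L, and the daily-activity preset uses 96-point segments
(16 h ≈ 190 L there). Velocities, when modelled instead of positions, are
forward differences assigned to the left timestamp — the causal stencil
matching the OU velocity interpretation.

## Synthetic generators

All generators are pure functions of (config, seed) and use the exact OU
transition with parameters frozen at the left endpoint of each step, so
constant-parameter runs have no discretization bias (steps larger than
10/ν log a warning). The SDE is the standard OU form above.

* **Daily activity**: σ(t) is a 24-h sawtooth — base 0.5, rising linearly
  from 5 am to a peak of 3.0 at 5 pm, dropping sharply back — convolved
  with a circular Gaussian smoother (width 1 h); the circular
  normalized-weight convolution preserves the daily mean exactly, and
  width 0 returns the raw wave. ν = 12 h⁻¹ and the mean at the origin are
  held fixed. The sawtooth levels and smoothing width are package
  defaults (configurable, recorded in output metadata); fits are judged
  by recovered-versus-generated functions, not by any external axis
  values. Default dataset: 10 days at 10-minute fixes (n = 1441).
* **Migration**: mean location (0, m_y(t)) with
  `g(t) = 1 + cos(2πt)·sqrt((1+b²)/(1+b²cos²(2πt)))` (b = 5) and
  `m_y = (5 − e^{−t/3}) g(t)`: an annual north–south oscillation whose
  northern endpoint climbs from 8 toward 10 while the south stays at 0.
  The walker tracks it with ν = 50 yr⁻¹ (~1-week reversion) and η = 3
  (~0.3 stationary spread). Default dataset: 3 years of weekly fixes.
* **Simulation from inferred latents**: per simulated day one posterior
  draw of (σ(·), L(·)) is selected; velocity follows an OU process with
  ν = 1/L(t) and stationary amplitude σ(t); positions are the integrated
  velocities, down-sampled to the collar schedule.

What the generators deliberately omit — terrain and boundaries, site
fidelity, social interaction, irregular fix gaps — bounds what passing
tests show: recovery and convergence results demonstrate the estimator
works when the model class contains the truth, not that real trajectories
satisfy these assumptions. The step/turn posterior predictive check
exists precisely to expose such mismatches on real data (momentum models
under-produce the near-π reversals that environmental features induce,
a property the tests reproduce).

## Posterior predictive checks

Trajectories are resampled at fixed windows (2 h, 4 h), taking the
nearest fix within 10% of the window at each boundary and breaking the
sequence where none exists. Steps are Euclidean displacements between
consecutive resampled points; turns are signed angles in (−π, π] from
planar cross/dot products. Comparison reports step-length quantiles, the
two-sample KS distance, and a total-variation distance between circular
turn histograms (24 bins) — a report, not a verdict.

## Experiment scales and known limitations

The packaged experiment presets are desk-scale: daily activity — 10 days
× 144 fixes/day, 4 chains × 10 000 steps (2 500 burn-in, thin 15);
migration — 157 weekly fixes, 4 chains × 16 000 steps (4 000 burn-in,
thin 24). Each fit takes minutes on one CPU. Larger problems scale
through longer segments and more chains, at cubic cost in segment length.

The migration design is deliberately coarse (weekly fixes against a
~1-week reversion time), which leaves the movement lengthscale below the
fix interval unidentified: θ̂ lands at a small L with σ absorbing part
of the spread, and the credible band for the route covers the *effective
lagged mean* of the walker rather than the generating mean (the walker
trails a fast-moving route by roughly speed/ν). Convergence diagnostics
are unaffected; point recovery of (σ, L) at this design is not a claim
the package makes.

Freezing hyperparameters at θ̂ also narrows credible bands — they carry
no hyperparameter uncertainty — so band coverage of a true latent
function sits near, not comfortably above, its nominal level on
realization-to-realization variation.

Limitations: fixed-metric preconditioning is only as good as the Laplace
approximation, and jointly sampling weakly identified hyperparameters on
small data mixes slowly (mitigated by MAP starts, hyper-groups, or
freezing θ̂); the subset-of-regressors interpolation understates latent
uncertainty between support points when spacing approaches the latent
lengthscale; measurement-error handling assumes iid Gaussian noise;
inputs are assumed planar (no projection handling) and gap-free.
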