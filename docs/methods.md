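# Methods

## Model

Atopic-dermatitis (AD) severity scores — EASI, SCORAD, oSCORAD, POEM — are
bounded composite instruments measured at clinic visits. The package models
each score independently as a noisy, bounded measurement of a latent
disease-severity process with patient-specific AR(1) dynamics on a regular
2-week grid (t = 0..12, week = 2t):

- Latent dynamics: `Ŝ_k(t+1) ~ N(α_k Ŝ_k(t) + b_k + x_kᵀβ, σ_l²)`, with
  autocorrelation `α_k ∈ (0, 1)` and intercept `b_k` per patient k, drawn
  from population hierarchies, and an optional linear effect of the
  standardized baseline covariates `x_k` (26 log-normal serum biomarkers,
  FLG mutation status, treatment arm, sex, age; D = 30).
- Measurement: `S_k(t) ~ N_[0,M](Ŝ_k(t), σ_m²)`, a Gaussian truncated to the
  score range [0, M] (M = 72 EASI, 83 oSCORAD, 103 SCORAD, 28 POEM).
  Grid cells without a measurement (the unvisited weeks 6, 10, 14–22, and
  missed visits) contribute no measurement term: missingness is handled as
  absence of measurement, not imputation.
- Covariate selection: `β` carries a regularized horseshoe prior
  (per-coefficient half-Cauchy local scales, half-Cauchy global scale, and a
  Student-t slab via an inverse-gamma–distributed slab width), which shrinks
  irrelevant coefficients to zero while leaving genuine signals nearly
  unshrunk.

## Priors and parameterization

Exact weakly-informative prior choices are the package's own; they are
deliberately scaled to the score range M:

| parameter | prior | default rationale |
|---|---|---|
| `μ_α` (logit scale) | N(1, 1) | centres E[α_k] near 0.7 |
| `σ_α` | half-N(1) | logit-scale spread |
| `μ_b` | N(0, 0.1·M) | intercepts are small score shifts |
| `σ_b` | half-N(0.05·M) | |
| `σ_l`, `σ_m` | half-N(0.1·M) | weakly informative on the score range |
| `Ŝ_k(0)` | Uniform[0, M] | no information before week 0 |
| horseshoe | p0 = 5, slab scale 2, slab df 4 | ~5 relevant covariates a priori; one covariate SD moves the drift by at most a few score units |

The horseshoe global scale is `τ ~ C⁺(0, τ₀)` with
`τ₀ = p0/(D−p0) · σ̃/√n` (σ̃ = 0.05·M, n = number of grid transitions).

Inference runs on an unconstrained space: non-centred hierarchies for
(α_k, b_k), non-centred innovation form for the latent states
(`Ŝ` reconstructed deterministically from standard-normal innovations),
log-transformed scales, logit-transformed α and initial state. This
removes the classic funnel geometries and makes the posterior close to
standard normal in most coordinates.

## Sampler

No probabilistic-programming backend is used: the joint log density and its
gradient are coded analytically (verified against finite differences in the
test suite) and sampled with an adaptive Hamiltonian Monte Carlo sampler —
dual-averaging step-size adaptation to a 0.8 acceptance target, a diagonal
mass matrix estimated from the middle half of warmup, and a jittered
leapfrog count (16–32 steps). Defaults are 4 chains × 2000 iterations with
50% warmup (4000 retained draws); reduced settings (2 × 400–1000) are used
inside cross-validation loops. Convergence is monitored with split R-hat
and bulk ESS (via arviz); a fit warns when any monitored R-hat exceeds 1.05
or ESS falls below 100. ESS is reported capped at the total draw count.

## Forecasting and scoring

A forecast for patient k, h steps past the last observed time, is the
equal-weight mixture over posterior draws of truncated-normal measurement
densities centred at the draw's latent state at the target time (the
sampled latent trajectory already propagates transition noise through
unobserved cells). Forecast quality is scored by the log predictive density
(lpd, mixture density then log, floored at 1e-300) and by the RMSE of the
predictive mean (closed-form truncated-normal means averaged over draws).

Validation is patient-stratified K-fold cross-validation (default K = 7)
with forward chaining: a test patient's visits are revealed one at a time,
the model is refitted on all training-fold data plus the revealed history,
and the next unrevealed visit is scored. On the full schedule the next-visit
horizons are (1, 1, 2, 2, 6) grid steps. A cheap `refit="filter"` mode
(one fit per fold; later forecasts by per-draw Kalman filtering with frozen
parameters) exists for small smoke runs; the faithful full-refit mode is
the default. Learning curves restrict to horizon-1 records (the package's
horizon adjustment — a reconstruction, since several equivalent adjustments
exist); aggregate SEs come from patient-level variation, and RMSE SEs from
a seeded patient-level bootstrap (500 resamples).

Reference models share the same Bayesian engine and scoring so that
comparisons isolate model structure: a uniform density 1/M; a random walk
with per-step increment SD fitted by maximum likelihood; a population AR(1)
(α unconstrained, so α = 1 nests the random walk); and a mixed-effect AR(1)
with hierarchical (α_k, b_k) directly on the observed scores. Visit gaps
compound the one-step models over intermediate 2-week steps (computed by
explicit polynomial sums, which avoids the α → 1 singularity).

## Synthetic cohorts

The generator draws from the model itself at the study's design dimensions:
42 patients; biomarkers multivariate log-normal with exchangeable
correlation 0.3 on the log scale; FLG prevalence 0.25, two equal treatment
arms, balanced sex, age ~ N(40, 12²) years; visits at weeks
{0, 2, 4, 8, 12, 24} (7 of 13 grid cells structurally missing, 53.8%), plus
optional random missed visits (5% reproduces the study's ~56% overall
missingness). Population defaults: `μ_α = 1.0`, `σ_α = 0.7` on the logit
scale (E[α_k] ≈ 0.7, draws essentially within (0.3, 1.0)); `b_k ~ N(1, 0.5²)`
score units; `σ_l = 1`, `σ_m = 3` (measurement share of one-step predictive
variance σ_m²/(σ_m²+σ_l²) = 90%); initial severities uniform on
[0.3M, 0.9M] (a moderate-to-severe cohort that mostly improves toward the
stationary level b/(1−α) ≈ 3). The default β is zero (the null-biomarker
scenario); sparse alternatives place ±2 score units per covariate SD at
seeded positions.

The simulator clips latent states into [0, M] after each transition
(severity is physically bounded), while the inference model treats the
latent state as unbounded with a bounded measurement — the two conventions
coincide whenever trajectories stay away from the bounds, which the default
regimes ensure. What the generator does **not** emulate: real biomarker
marginals or covariance structure, informative missingness, rater drift, or
any treatment-by-time interaction. Passing tests on these cohorts therefore
demonstrate correctness of the machinery and self-consistency of the model,
not clinical validity on real data.

## Variance decomposition

The reported "measurement share of predictive variance" is
`σ_m² / (σ_m² + σ_l²)` per draw (posterior mean and central 90% interval):
the one-step conditional predictive variance split with truncation ignored.
This is the simplest operationalization; an empirical posterior-predictive
variant would differ only near the score bounds.

## Numerical choices

- Truncated-normal log densities use `log_ndtr` with a symmetric
  complementary form so the normalizer is accurate when both bounds fall in
  the same Gaussian tail; closed-form truncated moments switch to
  exponential-tail asymptotics beyond 30 standardized units.
- Proposals with non-finite density or absurd magnitudes (|log-scale| > 30)
  are rejected before overflow; trajectories with energy error > 1000 count
  as divergences.
- Credible intervals are central (equal-tailed) at 90% everywhere.
- z-scoring uses the sample (n−1) SD; standardization uses observed values
  only, then imputes 0 (equivalent to raw-scale mean imputation).
- Binary codings: FLG mutation = 1; methotrexate = 1, azathioprine = 0;
  male = 1. Arbitrary but fixed; coefficients are sign-symmetric under
  recoding.

## Problem sizes in tests and the acceptance script

Forward chaining with full refits is expensive (one MCMC fit per fold per
revealed visit), so the automated checks run at reduced sizes chosen to
keep the statistical content intact: parameter-recovery replicates use 20
patients (2 chains × 1000 iterations), the model-ordering comparison 12
patients with 3 folds, the null-biomarker verdict 14 patients with 2 folds
and the full 30-covariate design, and the Kalman-equivalence check a single
patient with 4 × 2000 iterations. The analysis scripts under `analysis/`
run slightly larger versions of the same computations.

## Known limitations

- Static-trajectory HMC (no U-turn criterion) mixes the scale parameters
  σ_l, σ_m more slowly than NUTS would; ESS per iteration is modest and
  small runs can flag ESS < 100 on those coordinates.
- σ_l and σ_m are only weakly separated by 6 visits per patient; their
  posteriors are prior-sensitive in small cohorts (coverage, not precision,
  is what the recovery tests check).
- A patient-constant covariate effect competes with the intercept hierarchy;
  covariate signals are identifiable only with enough patients (the
  horseshoe signal-preservation test uses 30).
- Filter-mode forward chaining freezes population and patient parameters
  after the first revealed visit of each fold and ignores truncation in the
  Kalman update; it is a smoke-run approximation, not the evaluation mode.
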