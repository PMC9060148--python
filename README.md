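# eczema-ssm

Bayesian state-space modelling and probabilistic forecasting of
atopic-dermatitis (AD) severity trajectories, with a test of whether
baseline serum biomarkers are *predictive* — i.e. whether including them
improves out-of-sample forecasts of future severity, rather than merely
being associated with outcomes.

The package is aimed at biostatisticians and computational dermatology
researchers analysing longitudinal severity panels (EASI, SCORAD, oSCORAD,
POEM) from small cohorts with irregular visit schedules and substantial
missingness.

## Model

For each severity scale with maximum M, patient k's latent severity
`Ŝ_k(t)` on a 2-week grid follows a mixed-effect AR(1),

    Ŝ_k(t+1) ~ N( α_k Ŝ_k(t) + b_k + x_kᵀβ ,  σ_l² )

with patient-level autocorrelation `α_k ∈ (0,1)` and intercept `b_k` under
population hierarchies, and the observed score is a bounded, noisy
measurement,

    S_k(t) ~ N_[0,M]( Ŝ_k(t) ,  σ_m² )        (M = 72 for EASI, ...)

at visit weeks only; unvisited grid cells are simply absent measurements.
The baseline covariates `x_k` (26 log-transformed, z-scored serum
biomarkers plus FLG mutation status, treatment arm, sex and age; D = 30)
enter through `β` under a regularized horseshoe prior, so the model itself
performs covariate selection. Inference is Hamiltonian Monte Carlo on an
analytically differentiated joint posterior; forecasts are posterior
mixtures of truncated normals, scored by log predictive density (lpd) in
patient-stratified, forward-chaining cross-validation against four
reference forecasters (uniform, random walk, AR(1), mixed-effect AR(1)).

See `docs/methods.md` for priors, parameterization, the sampler, and what
the synthetic cohorts do and do not emulate.

## Worked example

```python
from eczema_ssm import (SimulationConfig, draw_true_parameters, simulate_dataset,
                        ModelSpec, MCMCConfig, fit, variance_decomposition,
                        make_folds, forward_chain_evaluate)

cfg = SimulationConfig(seed=7)   # study dimensions: 42 patients, EASI
ds, _ = simulate_dataset(draw_true_parameters(cfg), cfg)
post = fit(ds, ModelSpec(scale=ds.scale),
           MCMCConfig(n_chains=2, n_iterations=1000, seed=0))
frac, (lo, hi) = variance_decomposition(post)
print(f"measurement share of predictive variance: "
      f"{100*frac:.1f}% (90% CI {100*lo:.1f}-{100*hi:.1f}%)")

small = SimulationConfig(n_patients=12, n_biomarkers=2, seed=7)
ds, _ = simulate_dataset(draw_true_parameters(small), small)
folds = make_folds(ds, 3, seed=1)
mcmc = MCMCConfig(n_chains=2, n_iterations=500, seed=2)
for kind in ("uniform", "rw", "ar", "mixedar", "ssm"):
    rec = forward_chain_evaluate(kind, ds, folds, mcmc)
    print(f"{kind:8s} mean held-out lpd = {rec['lpd'].mean():.3f}")
```

prints

```
measurement share of predictive variance: 79.9% (90% CI 43.3-99.7%)
uniform  mean held-out lpd = -4.277
rw       mean held-out lpd = -3.695
ar       mean held-out lpd = -2.940
mixedar  mean held-out lpd = -2.840
ssm      mean held-out lpd = -2.841
```

The cohort is generated with σ_m = 3, σ_l = 1 (true measurement share
90%): the posterior mean is pulled below truth by this particular draw of
the cohort, but the 90% interval covers it — six visits per patient only
weakly separate latent from measurement noise, which is exactly why the
model quantifies the split with uncertainty. The uniform forecast scores
exactly −log 72 ≈ −4.277 on EASI; each richer forecaster improves the
held-out lpd, with the mixed-effect AR and the state-space model
essentially tied at this small size (the SSM's edge grows with cohort
size). The numbered scripts under `analysis/` run the full sequence
(simulate cohort → baseline fit → model comparison → biomarker verdict)
and write tables and figures under `results/`.

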