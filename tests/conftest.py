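import numpy as np
import pandas as pd
import pytest

from eczema_ssm import (
    SimulationConfig,
    draw_true_parameters,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six simulated patients with four biomarkers (EASI scale)."""
    cfg = SimulationConfig(n_patients=6, n_biomarkers=4, seed=11)
    tp = draw_true_parameters(cfg)
    ds, latent = simulate_dataset(tp, cfg)
    return cfg, tp, ds, latent


@pytest.fixture()
def toy_csvs(tmp_path):
    """A two-patient EASI dataset on disk (visits at weeks 0 and 2)."""
    sev = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p2"],
            "week": [0, 2, 0, 2],
            "value": [30.0, 25.0, 50.0, 48.0],
        }
    )
    cov = pd.DataFrame(
        {
            "patient_id": ["p1", "p2"],
            "il4": [1.2, 3.4],
            "il13": [0.5, 0.9],
            "flg": [0, 1],
            "treatment": [1, 0],
            "sex": [0, 1],
            "age": [35.0, 52.0],
        }
    )
    sev_path = tmp_path / "severity.csv"
    cov_path = tmp_path / "covariates.csv"
    sev.to_csv(sev_path, index=False)
    cov.to_csv(cov_path, index=False)
    return sev_path, cov_path


def make_fake_posterior(n_chains=2, n_draws=100, n_patients=3, n_cov=0, seed=0,
                        sigma_l=1.0, sigma_m=3.0):
    """A hand-built PosteriorSamples for summary-function unit tests."""
    from eczema_ssm import LongitudinalDataset, ObservationGrid, PatientRecord
    from eczema_ssm.scales import get_scale
    from eczema_ssm.ssm import MCMCConfig, ModelSpec, PosteriorSamples
    from eczema_ssm.data import N_GRID

    rng = np.random.default_rng(seed)
    scale = get_scale("EASI")
    C, N, K = n_chains, n_draws, n_patients
    d = n_cov if n_cov else 1
    names = [f"c{j}" for j in range(d)]
    patients = [
        PatientRecord(
            f"P{i}",
            rng.standard_normal(d) if n_cov else np.zeros(1),
            names,
        )
        for i in range(K)
    ]
    values = np.full((K, N_GRID), np.nan)
    values[:, 0] = 30.0
    values[:, 1] = 28.0
    ds = LongitudinalDataset(scale=scale, patients=patients,
                             grid=ObservationGrid(values, scale))
    params = {
        "mu_alpha": rng.normal(1.0, 0.1, (C, N)),
        "sigma_alpha": np.abs(rng.normal(0.5, 0.05, (C, N))),
        "mu_b": rng.normal(1.0, 0.1, (C, N)),
        "sigma_b": np.abs(rng.normal(0.5, 0.05, (C, N))),
        "sigma_l": sigma_l * (1.0 + 1e-9 * rng.random((C, N))),
        "sigma_m": sigma_m * (1.0 + 1e-9 * rng.random((C, N))),
        "alpha": np.clip(rng.normal(0.7, 0.05, (C, N, K)), 0.01, 0.99),
        "b": rng.normal(1.0, 0.2, (C, N, K)),
        "s0": rng.uniform(20, 50, (C, N, K)),
        "latent": rng.uniform(5, 60, (C, N, K, N_GRID)),
    }
    if n_cov:
        params["beta"] = rng.normal(0.0, 0.1, (C, N, n_cov))
    from eczema_ssm.ssm import HorseshoeConfig

    spec = ModelSpec(scale=scale, include_covariates=bool(n_cov),
                     n_covariates=n_cov,
                     horseshoe=HorseshoeConfig(p0=min(2, max(n_cov, 1))))
    mcmc = MCMCConfig(n_chains=C, n_iterations=2 * N, seed=seed)
    return PosteriorSamples(params=params, spec=spec, mcmc=mcmc, dataset=ds,
                            sampler_stats={})
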