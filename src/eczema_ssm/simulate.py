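"""Synthetic cohort generator for the severity state-space model.

Draws a cohort from the generative model itself — latent AR(1) severity
dynamics with patient-specific autocorrelation and intercept, optional
sparse covariate effects, and bounded (truncated-Gaussian) measurements on
the clinic-visit schedule — so that inference and validation can be tested
with known ground truth.

Default dimensions mirror the clinical study design: 42 patients, 26
correlated log-normal serum biomarkers, EASI measured at weeks
{0, 2, 4, 8, 12, 24} on a 2-week grid to week 24.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import expit

from .data import (
    GRID_WEEKS,
    N_GRID,
    SCHEDULED_WEEKS,
    LongitudinalDataset,
    ObservationGrid,
    PatientRecord,
    preprocess_covariates,
    week_to_index,
)
from .scales import SeverityScale, get_scale

import pandas as pd

__all__ = ["TrueParameters", "SimulationConfig", "draw_true_parameters",
           "simulate_dataset", "inject_missingness"]


@dataclass
class SimulationConfig:
    """Cohort design and generative hyperparameters.

    Population defaults give expected autocorrelation around 0.7 with
    patient draws spanning roughly (0.3, 1.0), intercepts near 1 score
    unit, and a measurement SD three times the latent-dynamics SD (the
    measurement process then accounts for ~90% of one-step predictive
    variance).  ``sparsity`` is the number of nonzero covariate
    coefficients; 0 reproduces the null-biomarker scenario.
    """

    n_patients: int = 42
    n_biomarkers: int = 26
    scale: SeverityScale = field(default_factory=lambda: get_scale("EASI"))
    biomarker_correlation: float = 0.3
    sparsity: int = 0
    seed: int = 0
    schedule: tuple[int, ...] = SCHEDULED_WEEKS
    mu_alpha: float = 1.0       # logit scale; E[alpha_k] ~ 0.7
    sigma_alpha: float = 0.7
    mu_b: float = 1.0           # score units
    sigma_b: float = 0.5
    sigma_l: float = 1.0
    sigma_m: float = 3.0
    beta_magnitude: float = 2.0  # effect of 1 covariate SD, score units
    s0_range: tuple[float, float] = (0.3, 0.9)  # fractions of max score

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 <= self.biomarker_correlation < 1:
            raise ValueError("biomarker_correlation must lie in [0, 1)")
        for w in self.schedule:
            week_to_index(w)

    @property
    def n_covariates(self) -> int:
        return self.n_biomarkers + 4  # + FLG, treatment, sex, age


@dataclass
class TrueParameters:
    """A complete generative parameter set (ground truth for recovery tests)."""

    mu_alpha: float
    sigma_alpha: float
    mu_b: float
    sigma_b: float
    beta: np.ndarray
    sigma_l: float
    sigma_m: float
    alpha: np.ndarray   # per patient, in (0, 1)
    b: np.ndarray       # per patient
    s0: np.ndarray      # initial latent states, in [0, M]

    def __post_init__(self) -> None:
        for name in ("sigma_alpha", "sigma_b", "sigma_l", "sigma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if np.any((self.alpha <= 0) | (self.alpha >= 1)):
            raise ValueError("alpha_k must lie in (0, 1)")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    def to_dict(self) -> dict:
        return {
            "mu_alpha": self.mu_alpha, "sigma_alpha": self.sigma_alpha,
            "mu_b": self.mu_b, "sigma_b": self.sigma_b,
            "beta": self.beta.tolist(), "sigma_l": self.sigma_l,
            "sigma_m": self.sigma_m, "alpha": self.alpha.tolist(),
            "b": self.b.tolist(), "s0": self.s0.tolist(),
        }


def draw_true_parameters(config: SimulationConfig) -> TrueParameters:
    """Draw patient-level parameters and a sparse coefficient vector.

    Deterministic given ``config.seed``.  Autocorrelations are drawn on the
    logit scale and mapped to (0, 1); exactly ``config.sparsity`` entries of
    beta are nonzero, at seeded positions, with alternating sign.
    """
    D = config.n_covariates
    if config.sparsity > D:
        raise ValueError(f"sparsity {config.sparsity} exceeds covariate count {D}")
    rng = np.random.default_rng(config.seed)
    K = config.n_patients
    alpha = expit(rng.normal(config.mu_alpha, config.sigma_alpha, size=K))
    b = rng.normal(config.mu_b, config.sigma_b, size=K)
    beta = np.zeros(D)
    if config.sparsity > 0:
        pos = rng.choice(D, size=config.sparsity, replace=False)
        signs = np.where(np.arange(config.sparsity) % 2 == 0, 1.0, -1.0)
        beta[pos] = config.beta_magnitude * signs
    M = config.scale.max_score
    lo, hi = config.s0_range
    s0 = rng.uniform(lo * M, hi * M, size=K)
    return TrueParameters(
        mu_alpha=config.mu_alpha, sigma_alpha=config.sigma_alpha,
        mu_b=config.mu_b, sigma_b=config.sigma_b, beta=beta,
        sigma_l=config.sigma_l, sigma_m=config.sigma_m,
        alpha=alpha, b=b, s0=s0,
    )


def simulate_latent_path(alpha, drift, sigma_l, s0, n_steps, rng,
                         bounds=None):
    """Iterate one latent AR(1) path: S(t+1) = alpha S(t) + drift + noise.

    ``bounds=(lo, hi)`` clips each state into the score range, as the
    cohort simulator does.  Returns an array of length ``n_steps + 1``.
    """
    path = np.empty(n_steps + 1)
    path[0] = s0
    for t in range(n_steps):
        nxt = alpha * path[t] + drift + sigma_l * rng.standard_normal()
        if bounds is not None:
            nxt = min(max(nxt, bounds[0]), bounds[1])
        path[t + 1] = nxt
    return path


def _simulate_covariates(config: SimulationConfig, rng: np.random.Generator):
    """Correlated multivariate log-normal biomarkers + demographics, then
    the same preprocessing as the real-data path."""
    K, P = config.n_patients, config.n_biomarkers
    rho = config.biomarker_correlation
    cov = np.full((P, P), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    log_bm = rng.standard_normal((K, P)) @ chol.T
    raw_bm = pd.DataFrame(np.exp(log_bm), columns=[f"bm_{j + 1}" for j in range(P)])
    flg = pd.Series(rng.random(K) < 0.25, dtype=float)      # mutation prevalence
    treatment = pd.Series(rng.random(K) < 0.5, dtype=float)  # methotrexate arm
    sex = pd.Series(rng.random(K) < 0.5, dtype=float)
    age = pd.Series(rng.normal(40.0, 12.0, size=K))          # adult cohort, years
    matrix, names, transform = preprocess_covariates(raw_bm, flg, treatment, sex, age)
    return matrix, names, transform, raw_bm


def simulate_dataset(
    true_params: TrueParameters, config: SimulationConfig
) -> tuple[LongitudinalDataset, np.ndarray]:
    """Simulate a cohort; returns (dataset, latent trajectory archive).

    Latent states are iterated on the full 13-point grid and clipped into
    [0, M] after each transition (severity is physically bounded);
    truncated-normal measurements are drawn at scheduled weeks only.  The
    returned archive holds the true latent states, shape (K, 13).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    K = config.n_patients
    M = config.scale.max_score
    X, names, transform, _ = _simulate_covariates(config, rng)
    effect = X @ true_params.beta

    S = np.empty((K, N_GRID))
    S[:, 0] = np.clip(true_params.s0, 0.0, M)
    for t in range(N_GRID - 1):
        mean = true_params.alpha * S[:, t] + true_params.b + effect
        S[:, t + 1] = np.clip(
            mean + true_params.sigma_l * rng.standard_normal(K), 0.0, M
        )

    values = np.full((K, N_GRID), np.nan)
    sm = true_params.sigma_m
    for w in config.schedule:
        t = week_to_index(w)
        if sm == 0:
            values[:, t] = np.clip(S[:, t], 0.0, M)
        else:
            a = (0.0 - S[:, t]) / sm
            b = (M - S[:, t]) / sm
            values[:, t] = stats.truncnorm.rvs(
                a, b, loc=S[:, t], scale=sm, size=K, random_state=rng
            )

    patients = [
        PatientRecord(f"P{(i + 1):03d}", X[i], names) for i in range(K)
    ]
    dataset = LongitudinalDataset(
        scale=config.scale,
        patients=patients,
        grid=ObservationGrid(values, config.scale),
        transform=transform,
    )
    return dataset, S


def inject_missingness(
    dataset: LongitudinalDataset, extra_missing_fraction: float, seed: int
) -> LongitudinalDataset:
    """Blank out a random fraction of the observed cells (missed visits)."""
    if not 0 <= extra_missing_fraction < 1:
        raise ValueError("extra_missing_fraction must lie in [0, 1)")
    if extra_missing_fraction == 0:
        return dataset
    rng = np.random.default_rng(seed)
    values = dataset.grid.values.copy()
    obs_idx = np.argwhere(~np.isnan(values))
    n_drop = int(round(extra_missing_fraction * len(obs_idx)))
    if n_drop:
        drop = rng.choice(len(obs_idx), size=n_drop, replace=False)
        values[obs_idx[drop, 0], obs_idx[drop, 1]] = np.nan
    return LongitudinalDataset(
        scale=dataset.scale,
        patients=dataset.patients,
        grid=ObservationGrid(values, dataset.scale),
        transform=dataset.transform,
    )


def save_ground_truth(true_params: TrueParameters, latent: np.ndarray,
                      out_dir: str | Path) -> Path:
    """Archive the generative parameters and true latent states as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "ground_truth.json"
    payload = true_params.to_dict()
    payload["latent_states"] = np.asarray(latent).tolist()
    payload["grid_weeks"] = list(GRID_WEEKS)
    path.write_text(json.dumps(payload, indent=2))
    return path
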