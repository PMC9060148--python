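"""Forward-chaining cross-validation and probabilistic forecast scoring.

Patients are partitioned into K folds (whole series stay together).  For
each fold, the test patients' histories are revealed one clinic visit at a
time; after each reveal the model is refitted on all training-fold data
plus the revealed test history and scored on each test patient's next
unrevealed visit with the log predictive density (lpd, mixture density
then log) and squared error of the predictive mean.  On the full visit
schedule the next-visit horizons are (1, 1, 2, 2, 6) grid steps for
targets at weeks 2, 4, 8, 12 and 24.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GRID_WEEKS, LongitudinalDataset
from .kalman import kalman_filter
from .predictive import TruncatedNormalMixture
from .reference import ARModel, MixedARModel, RandomWalkModel, UniformModel
from . import ssm as ssm_mod
from .ssm import MCMCConfig, ModelSpec

__all__ = [
    "MODEL_KINDS",
    "FoldAssignment",
    "PredictionRecord",
    "make_folds",
    "forward_chain_evaluate",
    "lpd_score",
    "rmse_score",
    "learning_curve",
    "horizon_curve",
]

MODEL_KINDS = ("uniform", "rw", "ar", "mixedar", "ssm")

RECORD_COLUMNS = [
    "model", "patient_id", "fold", "n_train_visits", "target_week",
    "horizon", "observed", "pred_mean", "lpd", "sq_err",
]


@dataclass
class FoldAssignment:
    """Seeded partition of patients into K folds of near-equal size."""

    n_folds: int
    assignment: dict[str, int]
    seed: int

    def fold_patients(self, fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f == fold]


@dataclass
class PredictionRecord:
    """One out-of-sample probabilistic forecast and its scores."""

    model: str
    patient_id: str
    fold: int
    n_train_visits: int
    target_week: int
    horizon: int
    observed: float
    pred_mean: float
    lpd: float
    sq_err: float


def make_folds(dataset: LongitudinalDataset, n_folds: int = 7,
               seed: int = 0) -> FoldAssignment:
    """Random patient-stratified partition; fold sizes differ by at most 1."""
    if n_folds > dataset.n_patients:
        raise ValueError("n_folds exceeds the number of patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(dataset.n_patients)
    assignment = {
        dataset.patient_ids[idx]: int(i % n_folds) for i, idx in enumerate(order)
    }
    return FoldAssignment(n_folds=n_folds, assignment=assignment, seed=seed)


def lpd_score(predictive, observed: float) -> float:
    """Log predictive density at the observation (density floor 1e-300)."""
    return float(predictive.logpdf(observed))


def _fit_model(kind: str, revealed: LongitudinalDataset,
               mcmc: MCMCConfig, spec: ModelSpec | None):
    scale = revealed.scale
    if kind == "uniform":
        return UniformModel(scale)
    if kind == "rw":
        return RandomWalkModel(scale).fit(revealed)
    if kind == "ar":
        return ARModel(scale).fit(revealed, mcmc)
    if kind == "mixedar":
        return MixedARModel(scale).fit(revealed, mcmc)
    if kind == "ssm":
        assert spec is not None
        return ssm_mod.fit(revealed, spec, mcmc)
    raise ValueError(f"unknown model kind {kind!r}; known: {MODEL_KINDS}")


def _predict_from(kind, fitted, k, last_value, h, t_prev, posterior_thin=None):
    if kind == "uniform":
        return fitted.predict()
    if kind in ("rw", "ar"):
        return fitted.predict(last_value, h)
    if kind == "mixedar":
        return fitted.predict(k, last_value, h)
    return ssm_mod.predict(fitted, k, h, from_time=t_prev)


def _ssm_filter_predictive(posterior, k, revealed_values, t_prev, h,
                           rng, n_components=500):
    """Cheap forecast update: per posterior draw, Kalman-filter the revealed
    history at fixed parameters (truncation ignored in the filter), propagate
    h steps, sample the latent endpoint and emit its measurement density."""
    M = posterior.spec.scale.max_score
    alpha = posterior.stacked("alpha")[:, k]
    b = posterior.stacked("b")[:, k]
    if "beta" in posterior.params:
        drift_extra = posterior.stacked("beta") @ posterior.dataset.patients[k].covariates
    else:
        drift_extra = np.zeros_like(b)
    sigma_l = posterior.stacked("sigma_l")
    sigma_m = posterior.stacked("sigma_m")
    n = alpha.size
    take = rng.choice(n, size=min(n_components, n), replace=False)
    locs = np.empty(take.size)
    scales = np.empty(take.size)
    y_hist = revealed_values[: t_prev + 1]
    for j, d in enumerate(take):
        mom = kalman_filter(
            y_hist, alpha[d], b[d] + drift_extra[d], sigma_l[d], sigma_m[d],
            init_mean=M / 2.0, init_var=M * M / 12.0,
        )
        m, v = mom.filt_mean[t_prev], mom.filt_var[t_prev]
        for _ in range(h):
            m = alpha[d] * m + b[d] + drift_extra[d]
            v = alpha[d] ** 2 * v + sigma_l[d] ** 2
        locs[j] = m + np.sqrt(v) * rng.standard_normal()
        scales[j] = sigma_m[d]
    return TruncatedNormalMixture(locs, scales, 0.0, M)


def forward_chain_evaluate(
    model_kind: str,
    dataset: LongitudinalDataset,
    folds: FoldAssignment,
    mcmc: MCMCConfig | None = None,
    spec: ModelSpec | None = None,
    refit: str = "full",
) -> pd.DataFrame:
    """Forward-chaining evaluation of one model; returns a record table.

    ``refit='full'`` refits after every revealed measurement (faithful to
    clinical use); ``refit='filter'`` fits once per fold at one revealed
    visit and only re-filters forecasts for later reveals (population and
    patient parameters frozen) — a cheap approximation for small runs.
    Fit failures are warned about and skipped; evaluation continues.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if refit not in ("full", "filter"):
        raise ValueError("refit must be 'full' or 'filter'")
    mcmc = mcmc or MCMCConfig()
    if model_kind == "ssm" and spec is None:
        spec = ModelSpec(scale=dataset.scale)
    pid_to_idx = {pid: i for i, pid in enumerate(dataset.patient_ids)}
    records: list[PredictionRecord] = []
    rng = np.random.default_rng(np.random.SeedSequence([folds.seed, 31]))

    for fold in range(folds.n_folds):
        test_idx = [pid_to_idx[p] for p in folds.fold_patients(fold)]
        n_visits = {k: dataset.grid.observed_times(k).size for k in test_idx}
        max_steps = max(n_visits.values()) - 1
        fold_fit = None
        for s in range(1, max_steps + 1):
            eligible = [k for k in test_idx if n_visits[k] >= s + 1]
            if not eligible:
                continue
            revealed = dataset.reveal_visits(test_idx, s)
            needs_fit = refit == "full" or fold_fit is None
            if needs_fit and model_kind != "uniform":
                try:
                    fold_fit = _fit_model(model_kind, revealed, mcmc, spec)
                except Exception as err:  # flagged, evaluation continues
                    warnings.warn(
                        f"{model_kind} fit failed at fold {fold} step {s}: {err}",
                        stacklevel=2,
                    )
                    continue
            elif model_kind == "uniform":
                fold_fit = _fit_model(model_kind, revealed, mcmc, spec)
            for k in eligible:
                t_obs = dataset.grid.observed_times(k)
                t_prev, t_next = int(t_obs[s - 1]), int(t_obs[s])
                h = t_next - t_prev
                y_next = float(dataset.grid.values[k, t_next])
                last_value = float(dataset.grid.values[k, t_prev])
                if model_kind == "ssm" and refit == "filter" and s > 1:
                    predictive = _ssm_filter_predictive(
                        fold_fit, k, revealed.grid.values[k], t_prev, h, rng
                    )
                elif model_kind == "mixedar" and refit == "filter" and s > 1:
                    predictive = fold_fit.predict(k, last_value, h)
                else:
                    predictive = _predict_from(
                        model_kind, fold_fit, k, last_value, h, t_prev
                    )
                mean = predictive.mean()
                records.append(PredictionRecord(
                    model=model_kind,
                    patient_id=dataset.patient_ids[k],
                    fold=fold,
                    n_train_visits=s,
                    target_week=GRID_WEEKS[t_next],
                    horizon=h,
                    observed=y_next,
                    pred_mean=mean,
                    lpd=lpd_score(predictive, y_next),
                    sq_err=(mean - y_next) ** 2,
                ))
    return pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)


def rmse_score(records: pd.DataFrame, n_boot: int = 500,
               seed: int = 0) -> tuple[float, float]:
    """RMSE of the predictive mean, with a patient-level bootstrap SE."""
    if len(records) == 0:
        raise ValueError("no prediction records")
    rmse = float(np.sqrt(records["sq_err"].mean()))
    rng = np.random.default_rng(seed)
    patients = records["patient_id"].unique()
    groups = {p: g["sq_err"].to_numpy() for p, g in records.groupby("patient_id")}
    boot = np.empty(n_boot)
    for i in range(n_boot):
        chosen = rng.choice(patients, size=patients.size, replace=True)
        vals = np.concatenate([groups[p] for p in chosen])
        boot[i] = np.sqrt(vals.mean())
    return rmse, float(boot.std(ddof=1))


def _group_curve(records: pd.DataFrame, by: str) -> pd.DataFrame:
    rows = []
    for key, g in records.groupby(by):
        patient_means = g.groupby("patient_id")["lpd"].mean()
        se = (
            float(patient_means.std(ddof=1) / np.sqrt(len(patient_means)))
            if len(patient_means) > 1 else np.nan
        )
        rows.append((key, float(g["lpd"].mean()), se, len(g)))
    return pd.DataFrame(rows, columns=[by, "mean_lpd", "se_lpd", "n_records"])


def learning_curve(records: pd.DataFrame,
                   horizon_adjustment: str = "restrict") -> pd.DataFrame:
    """Mean +/- SE lpd versus the number of prior visits.

    ``horizon_adjustment='restrict'`` keeps only one-step (2-week) records
    so that training size is not confounded with horizon; ``'none'`` pools
    all horizons.
    """
    if horizon_adjustment not in ("restrict", "none"):
        raise ValueError("horizon_adjustment must be 'restrict' or 'none'")
    if horizon_adjustment == "restrict":
        records = records[records["horizon"] == 1]
    if len(records) == 0:
        raise ValueError("no records after horizon adjustment")
    return _group_curve(records, "n_train_visits")


def horizon_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE lpd grouped by prediction horizon (2-week steps)."""
    if len(records) == 0:
        raise ValueError("no prediction records")
    return _group_curve(records, "horizon")
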