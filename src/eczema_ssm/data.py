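"""Longitudinal dataset containers, preprocessing and CSV I/O.

The study design observes each patient's severity score at clinic visits in
weeks {0, 2, 4, 8, 12, 24} while the dynamic model runs on a regular 2-week
grid over 24 weeks (13 time points, ``week = 2 t``).  Grid cells without a
scheduled visit (weeks 6, 10, 14, 16, 18, 20, 22) are therefore structurally
missing; additional cells may be missing because a visit was skipped.

Baseline covariates are 26 serum cytokine/chemokine concentrations
(log-transformed, then z-scored), filaggrin (FLG) mutation status, treatment
arm (methotrexate vs azathioprine), sex and z-scored age: D = 30 columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scales import SeverityScale, get_scale

__all__ = [
    "GRID_WEEKS",
    "SCHEDULED_WEEKS",
    "STRUCTURAL_MISSING_WEEKS",
    "N_GRID",
    "CovariateTransform",
    "ObservationGrid",
    "PatientRecord",
    "LongitudinalDataset",
    "preprocess_covariates",
    "align_to_grid",
    "load_dataset",
    "write_dataset",
    "read_dataset",
]

GRID_WEEKS: tuple[int, ...] = tuple(range(0, 26, 2))  # weeks 0..24, 2-week step
N_GRID: int = len(GRID_WEEKS)  # 13 grid cells, t = 0..12
SCHEDULED_WEEKS: tuple[int, ...] = (0, 2, 4, 8, 12, 24)
STRUCTURAL_MISSING_WEEKS: tuple[int, ...] = (6, 10, 14, 16, 18, 20, 22)


def week_to_index(week: int) -> int:
    """Map a calendar week to its grid index t (week = 2 t)."""
    if week % 2 != 0 or not 0 <= week <= GRID_WEEKS[-1]:
        raise ValueError(f"week {week} is off the 2-week grid [0, {GRID_WEEKS[-1]}]")
    return week // 2


@dataclass
class CovariateTransform:
    """Means and SDs used to standardize covariates, for audit and reuse.

    ``log_means``/``log_sds`` apply to the log-transformed biomarkers
    (sample SD, n-1 denominator); ``age_mean``/``age_sd`` to raw age.
    """

    biomarker_names: list[str]
    log_means: np.ndarray
    log_sds: np.ndarray
    age_mean: float
    age_sd: float
    n_imputed_biomarkers: int = 0
    n_imputed_flg: int = 0

    def to_dict(self) -> dict:
        return {
            "biomarker_names": list(self.biomarker_names),
            "log_means": self.log_means.tolist(),
            "log_sds": self.log_sds.tolist(),
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "n_imputed_biomarkers": self.n_imputed_biomarkers,
            "n_imputed_flg": self.n_imputed_flg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateTransform":
        return cls(
            biomarker_names=list(d["biomarker_names"]),
            log_means=np.asarray(d["log_means"], dtype=float),
            log_sds=np.asarray(d["log_sds"], dtype=float),
            age_mean=float(d["age_mean"]),
            age_sd=float(d["age_sd"]),
            n_imputed_biomarkers=int(d.get("n_imputed_biomarkers", 0)),
            n_imputed_flg=int(d.get("n_imputed_flg", 0)),
        )


@dataclass
class PatientRecord:
    """One patient's standardized baseline covariate vector."""

    patient_id: str
    covariates: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 1:
            raise ValueError("covariates must be a 1-D vector")
        if len(self.covariate_names) != self.covariates.size:
            raise ValueError("covariate_names length mismatch")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing/non-finite entries")


@dataclass
class ObservationGrid:
    """Patients x 2-week-grid matrix of (possibly missing) score values.

    ``values`` is (n_patients, 13) with NaN at missing cells;
    ``missing_mask`` is True where the cell is missing.
    """

    values: np.ndarray
    scale: SeverityScale

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_GRID:
            raise ValueError(f"grid must have {N_GRID} columns (weeks 0..24)")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (obs.min() < 0 or obs.max() > self.scale.max_score):
            raise ValueError(
                f"observations outside [0, {self.scale.max_score}] for "
                f"{self.scale.name}"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.missing_mask))

    def observed_times(self, patient_index: int) -> np.ndarray:
        """Grid indices with an observation, in increasing time order."""
        return np.flatnonzero(self.observed_mask[patient_index])


@dataclass
class LongitudinalDataset:
    """A severity-score panel plus the baseline covariate matrix."""

    scale: SeverityScale
    patients: list[PatientRecord]
    grid: ObservationGrid
    transform: CovariateTransform | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.grid.values.shape[0] != self.n_patients:
            raise ValueError("one grid row per patient required")
        lengths = {p.covariates.size for p in self.patients}
        if len(lengths) > 1:
            raise ValueError("covariate dimension differs across patients")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def covariate_matrix(self) -> np.ndarray:
        return np.vstack([p.covariates for p in self.patients])

    @property
    def covariate_names(self) -> list[str]:
        return list(self.patients[0].covariate_names)

    @property
    def n_covariates(self) -> int:
        return self.patients[0].covariates.size

    def subset(self, indices: Sequence[int]) -> "LongitudinalDataset":
        idx = list(indices)
        return LongitudinalDataset(
            scale=self.scale,
            patients=[self.patients[i] for i in idx],
            grid=ObservationGrid(self.grid.values[idx].copy(), self.scale),
            transform=self.transform,
        )

    def reveal_visits(self, patient_indices: Sequence[int], n_visits: int) -> "LongitudinalDataset":
        """Censor the listed patients down to their first ``n_visits`` visits.

        Used by forward chaining: a test patient's history is revealed one
        clinic visit at a time; everything later is masked out.
        """
        values = self.grid.values.copy()
        for i in patient_indices:
            t_obs = self.grid.observed_times(i)
            values[i, t_obs[n_visits:]] = np.nan
        return LongitudinalDataset(
            scale=self.scale,
            patients=self.patients,
            grid=ObservationGrid(values, self.scale),
            transform=self.transform,
        )


def preprocess_covariates(
    raw_biomarkers: pd.DataFrame,
    flg_status: pd.Series,
    treatment: pd.Series,
    sex: pd.Series,
    age: pd.Series,
) -> tuple[np.ndarray, list[str], CovariateTransform]:
    """Standardize baseline covariates into the model's design matrix.

    Biomarker concentrations are log-transformed then z-scored per column
    (sample SD); missing biomarker entries are imputed with the population
    mean, i.e. exactly 0 on the standardized scale.  Missing FLG status is
    imputed as "no mutation" (0).  Age is z-scored.  FLG / treatment / sex
    are 0/1 indicators (mutation=1; methotrexate=1, azathioprine=0; male=1).

    Returns (matrix, column names, transform record).
    """
    bm = raw_biomarkers.astype(float)
    if (bm <= 0).any().any():
        bad = bm.columns[(bm <= 0).any()].tolist()
        raise ValueError(f"non-positive biomarker concentrations in {bad}")
    log_bm = np.log(bm)
    means = log_bm.mean(axis=0, skipna=True)
    sds = log_bm.std(axis=0, ddof=1, skipna=True)
    degenerate = sds[(sds == 0) | sds.isna()].index.tolist()
    if degenerate:
        raise ValueError(f"degenerate (constant or all-missing) biomarker columns: {degenerate}")
    z = (log_bm - means) / sds
    n_imputed = int(z.isna().sum().sum())
    z = z.fillna(0.0)  # population-mean imputation on the standardized scale

    n_imputed_flg = int(flg_status.isna().sum())
    flg = flg_status.fillna(0).astype(float).to_numpy()
    treat = treatment.astype(float).to_numpy()
    sx = sex.astype(float).to_numpy()
    for name, col in (("flg", flg), ("treatment", treat), ("sex", sx)):
        if not np.isin(col, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be coded 0/1")

    age_f = age.astype(float)
    if age_f.isna().any():
        raise ValueError("age has missing entries")
    age_mean = float(age_f.mean())
    age_sd = float(age_f.std(ddof=1))
    if age_sd == 0:
        raise ValueError("degenerate (constant) age column")
    age_z = ((age_f - age_mean) / age_sd).to_numpy()

    matrix = np.column_stack([z.to_numpy(), flg, treat, sx, age_z])
    names = list(bm.columns) + ["FLG", "treatment", "sex", "age"]
    transform = CovariateTransform(
        biomarker_names=list(bm.columns),
        log_means=means.to_numpy(),
        log_sds=sds.to_numpy(),
        age_mean=age_mean,
        age_sd=age_sd,
        n_imputed_biomarkers=n_imputed,
        n_imputed_flg=n_imputed_flg,
    )
    return matrix, names, transform


def align_to_grid(
    observations: pd.DataFrame,
    patient_ids: Sequence[str],
    scale: SeverityScale,
) -> ObservationGrid:
    """Place long-format (patient_id, week, value) rows on the 13-cell grid.

    Weeks must be even and within [0, 24]; any grid cell without a row is
    missing, which includes the seven structurally unvisited weeks.
    """
    values = np.full((len(patient_ids), N_GRID), np.nan)
    order = {pid: i for i, pid in enumerate(patient_ids)}
    seen: set[tuple[str, int]] = set()
    for row in observations.itertuples(index=False):
        pid, week, value = str(row.patient_id), int(row.week), float(row.value)
        if pid not in order:
            raise ValueError(f"unknown patient_id {pid!r} in severity table")
        t = week_to_index(week)
        if (pid, t) in seen:
            raise ValueError(f"duplicate observation for patient {pid!r} week {week}")
        seen.add((pid, t))
        scale.validate_value(value)
        values[order[pid], t] = value
    return ObservationGrid(values, scale)


_SEVERITY_COLUMNS = ("patient_id", "week", "value")


def load_dataset(
    severity_csv_path: str | Path,
    covariate_csv_path: str | Path,
    scale_name: str,
) -> LongitudinalDataset:
    """Load and validate a dataset from a long severity CSV and a wide
    covariate CSV (columns: patient_id, <biomarkers...>, flg, treatment,
    sex, age).  Covariates are preprocessed; severity values are checked
    against the scale bounds and the 2-week grid.
    """
    scale = get_scale(scale_name)
    sev = pd.read_csv(severity_csv_path)
    missing_cols = set(_SEVERITY_COLUMNS) - set(sev.columns)
    if missing_cols:
        raise ValueError(f"severity CSV lacks columns {sorted(missing_cols)}")
    cov = pd.read_csv(covariate_csv_path)
    meta_cols = {"patient_id", "flg", "treatment", "sex", "age"}
    missing_cols = meta_cols - set(cov.columns)
    if missing_cols:
        raise ValueError(f"covariate CSV lacks columns {sorted(missing_cols)}")
    if cov["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in covariate CSV")
    patient_ids = [str(p) for p in cov["patient_id"]]
    biomarker_cols = [c for c in cov.columns if c not in meta_cols]
    matrix, names, transform = preprocess_covariates(
        cov[biomarker_cols], cov["flg"], cov["treatment"], cov["sex"], cov["age"]
    )
    patients = [
        PatientRecord(pid, matrix[i], names) for i, pid in enumerate(patient_ids)
    ]
    grid = align_to_grid(sev, patient_ids, scale)
    return LongitudinalDataset(scale=scale, patients=patients, grid=grid, transform=transform)


def write_dataset(dataset: LongitudinalDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialize the canonical (already-preprocessed) dataset.

    Writes ``severity.csv`` (long format), ``covariates_standardized.csv``
    and ``metadata.json`` (scale + transform record).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pid in enumerate(dataset.patient_ids):
        for t in dataset.grid.observed_times(i):
            rows.append((pid, GRID_WEEKS[t], dataset.grid.values[i, t]))
    sev_path = out / "severity.csv"
    pd.DataFrame(rows, columns=list(_SEVERITY_COLUMNS)).to_csv(sev_path, index=False)
    cov_path = out / "covariates_standardized.csv"
    cov_df = pd.DataFrame(dataset.covariate_matrix, columns=dataset.covariate_names)
    cov_df.insert(0, "patient_id", dataset.patient_ids)
    cov_df.to_csv(cov_path, index=False)
    meta_path = out / "metadata.json"
    meta = {
        "scale": dataset.scale.name,
        "max_score": dataset.scale.max_score,
        "n_patients": dataset.n_patients,
        "transform": dataset.transform.to_dict() if dataset.transform else None,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"severity": sev_path, "covariates": cov_path, "metadata": meta_path}


def read_dataset(in_dir: str | Path) -> LongitudinalDataset:
    """Inverse of :func:`write_dataset` (covariates are already standardized)."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "metadata.json").read_text())
    scale = get_scale(meta["scale"])
    cov = pd.read_csv(in_dir / "covariates_standardized.csv")
    patient_ids = [str(p) for p in cov["patient_id"]]
    names = [c for c in cov.columns if c != "patient_id"]
    matrix = cov[names].to_numpy(dtype=float)
    patients = [PatientRecord(pid, matrix[i], names) for i, pid in enumerate(patient_ids)]
    sev = pd.read_csv(in_dir / "severity.csv")
    grid = align_to_grid(sev, patient_ids, scale)
    transform = (
        CovariateTransform.from_dict(meta["transform"]) if meta.get("transform") else None
    )
    return LongitudinalDataset(scale=scale, patients=patients, grid=grid, transform=transform)
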