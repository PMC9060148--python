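"""Reporting figures: trajectory ribbons, coefficient forest, score curves.

Every number plotted is recomputable from the serialized artifacts
(posterior draws, prediction records, coefficient tables).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import GRID_WEEKS

__all__ = ["plot_trajectories", "plot_coefficient_forest", "plot_curves",
           "plot_reports"]

_RIBBON_LEVELS = (0.9, 0.7, 0.5, 0.3)


def plot_trajectories(posterior, patient_indices, path: str | Path) -> Path:
    """Stacked credible-interval ribbons of the posterior predictive
    measurement distribution per grid week, with observed scores overlaid."""
    from scipy import stats

    ds = posterior.dataset
    M = posterior.spec.scale.max_score
    sm = posterior.stacked("sigma_m")
    fig, axes = plt.subplots(
        1, len(patient_indices), figsize=(4 * len(patient_indices), 3.2),
        sharey=True, squeeze=False,
    )
    rng = np.random.default_rng(0)
    for ax, k in zip(axes[0], patient_indices):
        latent = posterior.stacked("latent")[:, k, :]  # (draws, T)
        n_sub = min(400, latent.shape[0])
        take = rng.choice(latent.shape[0], n_sub, replace=False)
        a = (0.0 - latent[take]) / sm[take, None]
        b = (M - latent[take]) / sm[take, None]
        y_draws = stats.truncnorm.rvs(
            a, b, loc=latent[take], scale=sm[take, None], random_state=rng
        )
        for lev, shade in zip(_RIBBON_LEVELS, np.linspace(0.15, 0.45, len(_RIBBON_LEVELS))):
            lo = np.quantile(y_draws, (1 - lev) / 2, axis=0)
            hi = np.quantile(y_draws, 1 - (1 - lev) / 2, axis=0)
            ax.fill_between(GRID_WEEKS, np.clip(lo, 0, M), np.clip(hi, 0, M),
                            color="C0", alpha=shade, linewidth=0)
        t_obs = ds.grid.observed_times(k)
        ax.plot(np.array(GRID_WEEKS)[t_obs], ds.grid.values[k, t_obs],
                "ko", markersize=4)
        ax.set_ylim(0, M)
        ax.set_xlabel("week")
        ax.set_title(ds.patient_ids[k])
    axes[0][0].set_ylabel(f"{posterior.spec.scale.name} score")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_coefficient_forest(coefficient_table: pd.DataFrame, path: str | Path) -> Path:
    """Forest plot of covariate coefficients (posterior mean, 90% CI)."""
    tab = coefficient_table.reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(tab) + 1.5))
    ypos = np.arange(len(tab))[::-1]
    ax.errorbar(
        tab["mean"], ypos,
        xerr=[tab["mean"] - tab["q5"], tab["q95"] - tab["mean"]],
        fmt="o", markersize=3, capsize=2, color="C0",
    )
    ax.axvline(0.0, color="grey", linewidth=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(tab["covariate"], fontsize=7)
    ax.set_xlabel("coefficient (score units per covariate SD)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_curves(records: pd.DataFrame, path: str | Path) -> Path:
    """Learning and horizon curves (mean +/- SE lpd) per model."""
    from .validation import horizon_curve, learning_curve

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for kind, g in records.groupby("model"):
        lc = learning_curve(g, horizon_adjustment="restrict")
        ax1.errorbar(lc["n_train_visits"], lc["mean_lpd"], yerr=lc["se_lpd"],
                     marker="o", label=kind)
        hc = horizon_curve(g)
        ax2.errorbar(hc["horizon"], hc["mean_lpd"], yerr=hc["se_lpd"],
                     marker="o", label=kind)
    ax1.set_xlabel("training visits")
    ax1.set_ylabel("lpd")
    ax1.set_title("learning curve (2-week-ahead)")
    ax2.set_xlabel("horizon (2-week steps)")
    ax2.set_title("horizon curve")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_reports(posterior=None, records: pd.DataFrame | None = None,
                 out_dir: str | Path = "figures",
                 coefficient_table: pd.DataFrame | None = None) -> dict:
    """Produce all available figures from the supplied artifacts."""
    if posterior is None and records is None and coefficient_table is None:
        raise ValueError("no artifacts to plot")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced = {}
    if posterior is not None:
        n_show = min(4, posterior.dataset.n_patients)
        produced["trajectories"] = plot_trajectories(
            posterior, list(range(n_show)), out / "trajectories.png"
        )
    if coefficient_table is not None:
        produced["forest"] = plot_coefficient_forest(
            coefficient_table, out / "coefficient_forest.png"
        )
    if records is not None and len(records):
        produced["curves"] = plot_curves(records, out / "curves.png")
    return {k: str(v) for k, v in produced.items()}
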