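"""Scalar Kalman filter for the linear-Gaussian limit of the state model.

When the measurement truncation is inactive (latent state far from the
score bounds relative to sigma_m), the state-space model is exactly a
linear-Gaussian AR(1)-plus-noise model, and its filtering and predictive
moments have the closed forms below.  Used as an independent oracle for
the MCMC path and for fast filter-only forecast updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KalmanMoments", "kalman_filter", "kalman_predict"]


@dataclass
class KalmanMoments:
    """Per-time prior (pre-update) and filtered (post-update) moments."""

    prior_mean: np.ndarray
    prior_var: np.ndarray
    filt_mean: np.ndarray
    filt_var: np.ndarray


def kalman_filter(
    y: np.ndarray,
    alpha: float,
    drift: float,
    sigma_l: float,
    sigma_m: float,
    init_mean: float,
    init_var: float,
) -> KalmanMoments:
    """Filter a single series with NaN marking missing observations.

    State: S(t+1) = alpha S(t) + drift + N(0, sigma_l^2);
    observation: y(t) = S(t) + N(0, sigma_m^2) where not NaN.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    pm = np.empty(T); pv = np.empty(T)
    fm = np.empty(T); fv = np.empty(T)
    m, v = float(init_mean), float(init_var)
    for t in range(T):
        if t > 0:
            m = alpha * m + drift
            v = alpha * alpha * v + sigma_l**2
        pm[t], pv[t] = m, v
        if np.isfinite(y[t]):
            gain = v / (v + sigma_m**2)
            m = m + gain * (y[t] - m)
            v = (1.0 - gain) * v
        fm[t], fv[t] = m, v
    return KalmanMoments(pm, pv, fm, fv)


def kalman_predict(
    filt_mean: float,
    filt_var: float,
    alpha: float,
    drift: float,
    sigma_l: float,
    sigma_m: float,
    horizon: int,
) -> tuple[float, float]:
    """Closed-form h-step-ahead observation predictive mean and variance."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    m, v = float(filt_mean), float(filt_var)
    for _ in range(horizon):
        m = alpha * m + drift
        v = alpha * alpha * v + sigma_l**2
    return m, v + sigma_m**2
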