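"""Posterior-predictive distributions on a bounded score range.

Forecasts are equal-weight mixtures over posterior draws of truncated
normal components on [0, M]; the uniform reference forecast is a single
flat density.  ``logpdf`` averages component densities before taking the
log (mixture density, then log), which is the quantity the log-predictive-
density scoring rule needs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, logsumexp

__all__ = [
    "truncnorm_logpdf",
    "truncnorm_mean_var",
    "TruncatedNormalMixture",
    "UniformPredictive",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
DENSITY_FLOOR = 1e-300


def _log_phi(x: np.ndarray) -> np.ndarray:
    return -_HALF_LOG_2PI - 0.5 * x * x


def _log_Z(a, b) -> np.ndarray:
    """log(Phi(b) - Phi(a)) for a < b, computed stably in both tails.

    When both bounds are positive the symmetric form
    Phi(-a) - Phi(-b) avoids catastrophic cancellation near Phi ~ 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = np.where(a > 0, -b, a)
    hi = np.where(a > 0, -a, b)
    l_lo, l_hi = log_ndtr(lo), log_ndtr(hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        return l_hi + np.log1p(-np.exp(l_lo - l_hi))


def truncnorm_logpdf(y, loc, scale, low: float, high: float):
    """Log density of N(loc, scale^2) truncated to [low, high] at y.

    The centre ``loc`` may lie outside the bounds; y must not.
    """
    y = np.asarray(y, dtype=float)
    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale must be > 0")
    if np.any((y < low) | (y > high)):
        raise ValueError(f"observation outside [{low}, {high}]")
    a = (low - loc) / scale
    b = (high - loc) / scale
    return _log_phi((y - loc) / scale) - np.log(scale) - _log_Z(a, b)


def truncnorm_mean_var(loc, scale, low: float, high: float):
    """Closed-form mean and variance of the [low, high]-truncated normal.

    Far outside the bounds (|standardized bound| > 30) the normalizer
    underflows; there the exponential-tail asymptotics are used instead
    (mass piles up against the nearer bound).
    """
    loc = np.atleast_1d(np.asarray(loc, dtype=float))
    scale = np.broadcast_to(np.atleast_1d(np.asarray(scale, dtype=float)), loc.shape)
    a = (low - loc) / scale
    b = (high - loc) / scale
    with np.errstate(all="ignore"):
        logZ = _log_Z(a, b)
        pa = np.exp(_log_phi(a) - logZ)
        pb = np.exp(_log_phi(b) - logZ)
        mean = loc + scale * (pa - pb)
        var = scale**2 * (1.0 + a * pa - b * pb - (pa - pb) ** 2)
    far_below = a > 30.0   # all mass hugs the lower bound
    far_above = b < -30.0  # all mass hugs the upper bound
    mean = np.where(far_below, low + scale / np.maximum(a, 1e-12), mean)
    var = np.where(far_below, (scale / np.maximum(a, 1e-12)) ** 2, var)
    mean = np.where(far_above, high + scale / np.minimum(b, -1e-12), mean)
    var = np.where(far_above, (scale / np.minimum(b, -1e-12)) ** 2, var)
    if mean.size == 1:
        return float(mean[0]), float(max(var[0], 0.0))
    return mean, np.maximum(var, 0.0)


class TruncatedNormalMixture:
    """Equal-weight mixture of truncated normals on [low, high]."""

    def __init__(self, locs, scales, low: float, high: float):
        self.locs = np.atleast_1d(np.asarray(locs, dtype=float))
        scales = np.asarray(scales, dtype=float)
        self.scales = np.broadcast_to(np.atleast_1d(scales), self.locs.shape).copy()
        if np.any(self.scales <= 0):
            raise ValueError("component scales must be > 0")
        self.low = float(low)
        self.high = float(high)

    @property
    def n_components(self) -> int:
        return self.locs.size

    def logpdf(self, y: float) -> float:
        comp = truncnorm_logpdf(y, self.locs, self.scales, self.low, self.high)
        val = logsumexp(comp) - np.log(self.n_components)
        return float(max(val, np.log(DENSITY_FLOOR)))

    def mean(self) -> float:
        m, _ = truncnorm_mean_var(self.locs, self.scales, self.low, self.high)
        return float(np.mean(m))

    def var(self) -> float:
        m, v = truncnorm_mean_var(self.locs, self.scales, self.low, self.high)
        return float(np.mean(v) + np.var(m))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        from scipy import stats

        idx = rng.integers(0, self.n_components, size=n)
        loc, sc = self.locs[idx], self.scales[idx]
        a = (self.low - loc) / sc
        b = (self.high - loc) / sc
        return stats.truncnorm.rvs(a, b, loc=loc, scale=sc, random_state=rng)

    def quantiles(self, qs, n_mc: int = 4000, seed: int = 0) -> np.ndarray:
        draws = self.sample(n_mc, np.random.default_rng(seed))
        return np.quantile(draws, qs)


class UniformPredictive:
    """Flat forecast density 1/M on [0, M] — the weakest reference model."""

    def __init__(self, max_score: float):
        if max_score <= 0:
            raise ValueError("max_score must be > 0")
        self.low = 0.0
        self.high = float(max_score)

    def logpdf(self, y: float) -> float:
        if not self.low <= y <= self.high:
            raise ValueError(f"observation outside [0, {self.high}]")
        return float(-np.log(self.high))

    def mean(self) -> float:
        return self.high / 2.0

    def var(self) -> float:
        return self.high**2 / 12.0

    def quantiles(self, qs, **_) -> np.ndarray:
        return self.high * np.asarray(qs, dtype=float)
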