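"""Reference forecasting models: uniform, random walk, AR(1), mixed-effect AR(1).

These are the comparison baselines for the state-space model.  All of them
forecast the observed score directly (no latent/measurement split):

- Uniform: flat density on [0, M]; ignores the data entirely.
- RW: random walk, increments N(0, sigma^2 h) over h grid steps; sigma by
  maximum likelihood on observed step increments.
- AR: population AR(1), S(t+1) ~ N(alpha S(t) + b, sigma^2), one parameter
  set shared by all patients, Bayesian fit by default.
- MixedAR: AR(1) with hierarchical patient-specific (alpha_k, b_k).

Visit gaps (weeks 4->8, 12->24) are handled by compounding the one-step
model over the intermediate 2-week grid steps, keeping the time scale
consistent with the state-space model.  Predictive densities are truncated
to [0, M] and renormalized at evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import LongitudinalDataset
from .hmc import sample_hmc
from .predictive import TruncatedNormalMixture, UniformPredictive
from .scales import SeverityScale
from .ssm import MCMCConfig, _halfnormal_logp_grad

__all__ = [
    "REFERENCE_KINDS",
    "UniformModel",
    "RandomWalkModel",
    "ARModel",
    "MixedARModel",
    "extract_transitions",
]

REFERENCE_KINDS = ("uniform", "rw", "ar", "mixedar")

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def extract_transitions(dataset: LongitudinalDataset):
    """All consecutive observed pairs per patient with their grid gap h.

    Returns (patient_index, y_prev, y_next, h) arrays.
    """
    ks, prevs, nexts, gaps = [], [], [], []
    for k in range(dataset.n_patients):
        t_obs = dataset.grid.observed_times(k)
        vals = dataset.grid.values[k, t_obs]
        for j in range(len(t_obs) - 1):
            ks.append(k)
            prevs.append(vals[j])
            nexts.append(vals[j + 1])
            gaps.append(int(t_obs[j + 1] - t_obs[j]))
    return (np.array(ks, dtype=int), np.array(prevs), np.array(nexts),
            np.array(gaps, dtype=int))


def _gap_sums(alpha: np.ndarray, h: np.ndarray):
    """Compounded AR(1) terms over h one-step transitions, with derivatives.

    A = alpha^h, S1 = sum_{i<h} alpha^i, S2 = sum_{i<h} alpha^{2i};
    primes are d/dalpha.  Computed by explicit summation (h is a small
    integer), which avoids the alpha -> 1 singularity of the closed forms.
    """
    alpha = np.asarray(alpha, dtype=float)
    h = np.asarray(h, dtype=int)
    A = alpha**h
    dA = h * alpha ** np.maximum(h - 1, 0)
    S1 = np.zeros_like(alpha); dS1 = np.zeros_like(alpha)
    S2 = np.zeros_like(alpha); dS2 = np.zeros_like(alpha)
    hmax = int(h.max())
    for i in range(hmax):
        active = h > i
        S1 += np.where(active, alpha**i, 0.0)
        S2 += np.where(active, alpha ** (2 * i), 0.0)
        if i >= 1:
            dS1 += np.where(active, i * alpha ** (i - 1), 0.0)
            dS2 += np.where(active, 2 * i * alpha ** (2 * i - 1), 0.0)
    return A, dA, S1, dS1, S2, dS2


class UniformModel:
    """The no-information forecaster: density 1/M on [0, M]."""

    kind = "uniform"

    def __init__(self, scale: SeverityScale):
        self.scale = scale

    def fit(self, dataset: LongitudinalDataset) -> "UniformModel":
        return self

    def predict(self, *_args, **_kwargs) -> UniformPredictive:
        return UniformPredictive(self.scale.max_score)


class RandomWalkModel:
    """Driftless random walk; sigma is the per-2-week-step increment SD,
    estimated by maximum likelihood: sigma^2 = mean over increments of
    (Delta y)^2 / h."""

    kind = "rw"

    def __init__(self, scale: SeverityScale):
        self.scale = scale
        self.sigma_: float | None = None

    def fit(self, dataset: LongitudinalDataset) -> "RandomWalkModel":
        _, prevs, nexts, gaps = extract_transitions(dataset)
        if prevs.size == 0:
            raise ValueError("random walk fit needs at least one observed increment")
        self.sigma_ = float(np.sqrt(np.mean((nexts - prevs) ** 2 / gaps)))
        self.sigma_ = max(self.sigma_, 1e-6 * self.scale.max_score)
        return self

    def predict(self, last_value: float, horizon: int) -> TruncatedNormalMixture:
        if self.sigma_ is None:
            raise ValueError("model not fitted")
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        return TruncatedNormalMixture(
            [last_value], [self.sigma_ * np.sqrt(horizon)], 0.0, self.scale.max_score
        )


class ARModel:
    """Population AR(1) with weakly informative priors, shared engine.

    Parameters (alpha, b, sigma); alpha is unconstrained (alpha = 1, b = 0
    recovers the random walk).  ``method='mle'`` gives the plug-in maximum
    a posteriori fit instead of posterior draws.
    """

    kind = "ar"

    def __init__(self, scale: SeverityScale, method: str = "bayes"):
        if method not in ("bayes", "mle"):
            raise ValueError("method must be 'bayes' or 'mle'")
        self.scale = scale
        self.method = method
        self.draws_: dict | None = None  # alpha, b, sigma arrays

    # theta = (alpha, b, log_sigma)
    def _logp_grad_factory(self, prevs, nexts, gaps):
        M = self.scale.max_score
        pb_scale = 0.1 * M

        def logp_grad(theta):
            alpha, b, ls = theta
            if not np.all(np.isfinite(theta)) or abs(ls) > 30 or abs(alpha) > 1e3:
                return -np.inf, np.zeros(3)
            sigma = np.exp(ls)
            A, dA, S1, dS1, S2, dS2 = _gap_sums(np.full_like(prevs, alpha), gaps)
            mean = A * prevs + b * S1
            V = sigma**2 * S2
            e = nexts - mean
            lp = float(np.sum(-_HALF_LOG_2PI - 0.5 * np.log(V) - 0.5 * e * e / V))
            dl_dmean = e / V
            dl_dV = -0.5 / V + 0.5 * e * e / (V * V)
            g_alpha = float(np.sum(dl_dmean * (dA * prevs + b * dS1)
                                   + dl_dV * sigma**2 * dS2))
            g_b = float(np.sum(dl_dmean * S1))
            g_ls = float(np.sum(dl_dV * 2.0 * V))
            # priors: alpha ~ N(0.5, 1), b ~ N(0, 0.1 M), sigma ~ HN(0.1 M)
            lp += -0.5 * (alpha - 0.5) ** 2
            g_alpha += -(alpha - 0.5)
            lp += -0.5 * (b / pb_scale) ** 2
            g_b += -b / pb_scale**2
            lp_s, g_s = _halfnormal_logp_grad(sigma, 0.1 * M)
            lp += lp_s
            g_ls += g_s
            return lp, np.array([g_alpha, g_b, g_ls])

        return logp_grad

    def fit(self, dataset: LongitudinalDataset,
            mcmc: MCMCConfig | None = None) -> "ARModel":
        _, prevs, nexts, gaps = extract_transitions(dataset)
        if prevs.size < 2:
            raise ValueError("AR fit needs at least 2 observed transitions")
        logp_grad = self._logp_grad_factory(prevs, nexts, gaps)
        mcmc = mcmc or MCMCConfig()
        if self.method == "mle":
            from scipy.optimize import minimize

            res = minimize(
                lambda th: -logp_grad(th)[0],
                x0=np.array([0.8, 0.5, np.log(0.05 * self.scale.max_score)]),
                jac=lambda th: -logp_grad(th)[1],
                method="L-BFGS-B",
            )
            self.draws_ = {
                "alpha": np.array([res.x[0]]),
                "b": np.array([res.x[1]]),
                "sigma": np.array([np.exp(res.x[2])]),
            }
            return self
        rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 23]))
        inits = np.vstack([
            np.array([0.8, 0.5, np.log(0.05 * self.scale.max_score)])
            + 0.05 * rng.standard_normal(3)
            for _ in range(mcmc.n_chains)
        ])
        result = sample_hmc(
            logp_grad, inits, n_iterations=mcmc.n_iterations,
            warmup=mcmc.n_warmup, seed=mcmc.seed,
            max_leapfrog=mcmc.max_leapfrog,
        )
        flat = result.draws.reshape(-1, 3)
        self.draws_ = {
            "alpha": flat[:, 0], "b": flat[:, 1], "sigma": np.exp(flat[:, 2])
        }
        return self

    def predict(self, last_value: float, horizon: int) -> TruncatedNormalMixture:
        if self.draws_ is None:
            raise ValueError("model not fitted")
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        alpha = self.draws_["alpha"]
        A, _, S1, _, S2, _ = _gap_sums(alpha, np.full(alpha.shape, horizon, dtype=int))
        locs = A * last_value + self.draws_["b"] * S1
        scales = self.draws_["sigma"] * np.sqrt(S2)
        return TruncatedNormalMixture(locs, scales, 0.0, self.scale.max_score)


class MixedARModel:
    """Hierarchical AR(1) on the observed scores (no measurement layer).

    This is the state-space model with the measurement SD collapsed to
    zero: patient-specific (alpha_k, b_k) under population hierarchies, one
    shared innovation SD.  The strongest reference model.
    """

    kind = "mixedar"

    def __init__(self, scale: SeverityScale,
                 prior_mu_alpha: tuple[float, float] = (1.0, 1.0)):
        self.scale = scale
        self.prior_mu_alpha = prior_mu_alpha
        self.draws_: dict | None = None
        self._n_patients: int | None = None

    # theta = (mu_a, log_sigma_a, mu_b, log_sigma_b, log_sigma, a_raw[K], b_raw[K])
    def _logp_grad_factory(self, K, ks, prevs, nexts, gaps):
        M = self.scale.max_score
        mloc, mscale = self.prior_mu_alpha
        pb_scale, psb_scale, ps_scale = 0.1 * M, 0.05 * M, 0.1 * M

        def logp_grad(theta):
            if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e4:
                return -np.inf, np.zeros_like(theta)
            mu_a, lsa, mu_b, lsb, ls = theta[:5]
            if max(abs(lsa), abs(lsb), abs(ls)) > 30:
                return -np.inf, np.zeros_like(theta)
            a_raw = theta[5 : 5 + K]
            b_raw = theta[5 + K : 5 + 2 * K]
            sigma_a, sigma_b, sigma = np.exp(lsa), np.exp(lsb), np.exp(ls)
            alpha_k = expit(mu_a + sigma_a * a_raw)
            b_k = mu_b + sigma_b * b_raw
            al = alpha_k[ks]
            A, dA, S1, dS1, S2, dS2 = _gap_sums(al, gaps)
            mean = A * prevs + b_k[ks] * S1
            V = sigma**2 * S2
            e = nexts - mean
            lp = float(np.sum(-_HALF_LOG_2PI - 0.5 * np.log(V) - 0.5 * e * e / V))
            dl_dmean = e / V
            dl_dV = -0.5 / V + 0.5 * e * e / (V * V)
            g_alpha_pair = dl_dmean * (dA * prevs + b_k[ks] * dS1) + dl_dV * sigma**2 * dS2
            g_b_pair = dl_dmean * S1
            g_alpha = np.bincount(ks, weights=g_alpha_pair, minlength=K)
            g_b = np.bincount(ks, weights=g_b_pair, minlength=K)
            g_ls = float(np.sum(dl_dV * 2.0 * V))

            grad = np.zeros_like(theta)
            g_a_lin = g_alpha * alpha_k * (1.0 - alpha_k)
            # priors
            lp += -0.5 * ((mu_a - mloc) / mscale) ** 2
            grad[0] = -(mu_a - mloc) / mscale**2 + np.sum(g_a_lin)
            lp_sa, g_lsa = _halfnormal_logp_grad(sigma_a, 1.0)
            lp += lp_sa
            grad[1] = g_lsa + sigma_a * float(a_raw @ g_a_lin)
            lp += -0.5 * (mu_b / pb_scale) ** 2
            grad[2] = -mu_b / pb_scale**2 + np.sum(g_b)
            lp_sb, g_lsb = _halfnormal_logp_grad(sigma_b, psb_scale)
            lp += lp_sb
            grad[3] = g_lsb + sigma_b * float(b_raw @ g_b)
            lp_s, g_s = _halfnormal_logp_grad(sigma, ps_scale)
            lp += lp_s
            grad[4] = g_s + g_ls
            lp += -0.5 * float(a_raw @ a_raw + b_raw @ b_raw)
            grad[5 : 5 + K] = sigma_a * g_a_lin - a_raw
            grad[5 + K : 5 + 2 * K] = sigma_b * g_b - b_raw
            return lp, grad

        return logp_grad

    def fit(self, dataset: LongitudinalDataset,
            mcmc: MCMCConfig | None = None) -> "MixedARModel":
        K = dataset.n_patients
        ks, prevs, nexts, gaps = extract_transitions(dataset)
        if prevs.size < 2:
            raise ValueError("mixed AR fit needs at least 2 observed transitions")
        logp_grad = self._logp_grad_factory(K, ks, prevs, nexts, gaps)
        mcmc = mcmc or MCMCConfig()
        rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 29]))
        base = np.concatenate([
            [1.0, np.log(0.3), 0.5, np.log(0.02 * self.scale.max_score),
             np.log(0.05 * self.scale.max_score)],
            np.zeros(2 * K),
        ])
        inits = np.vstack([
            base + 0.05 * rng.standard_normal(base.size)
            for _ in range(mcmc.n_chains)
        ])
        result = sample_hmc(
            logp_grad, inits, n_iterations=mcmc.n_iterations,
            warmup=mcmc.n_warmup, seed=mcmc.seed,
            max_leapfrog=mcmc.max_leapfrog,
        )
        flat = result.draws.reshape(-1, base.size)
        sigma_a = np.exp(flat[:, 1])
        self.draws_ = {
            "mu_alpha": flat[:, 0],
            "sigma_alpha": sigma_a,
            "mu_b": flat[:, 2],
            "sigma_b": np.exp(flat[:, 3]),
            "sigma": np.exp(flat[:, 4]),
            "alpha": expit(flat[:, 0:1] + sigma_a[:, None] * flat[:, 5 : 5 + K]),
            "b": flat[:, 2:3] + np.exp(flat[:, 3:4]) * flat[:, 5 + K : 5 + 2 * K],
        }
        self._n_patients = K
        return self

    def predict(self, patient_index: int, last_value: float,
                horizon: int) -> TruncatedNormalMixture:
        if self.draws_ is None:
            raise ValueError("model not fitted")
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        alpha = self.draws_["alpha"][:, patient_index]
        b = self.draws_["b"][:, patient_index]
        A, _, S1, _, S2, _ = _gap_sums(alpha, np.full(alpha.shape, horizon, dtype=int))
        locs = A * last_value + b * S1
        scales = self.draws_["sigma"] * np.sqrt(S2)
        return TruncatedNormalMixture(locs, scales, 0.0, self.scale.max_score)
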