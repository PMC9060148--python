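"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

A compact static-trajectory HMC sampler: dual-averaging step-size
adaptation toward a target acceptance rate, diagonal mass-matrix
estimation from the middle of warmup, and a jittered number of leapfrog
steps per iteration.  Models supply ``logp_and_grad(theta) -> (float,
ndarray)`` on an unconstrained space (transform Jacobians included).

This is deliberately simple — no U-turn criterion — but adequate for the
model sizes used here (a few hundred dimensions with benign, mostly
standard-normal geometry after non-centring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCResult", "sample_hmc"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    """Post-warmup draws, shape (n_chains, n_kept, dim), plus sampler stats."""

    draws: np.ndarray
    accept_rate: np.ndarray      # per chain
    step_size: np.ndarray        # adapted, per chain
    divergences: np.ndarray      # per chain
    logp: np.ndarray             # (n_chains, n_kept)


def _leapfrog(logp_grad: LogpGrad, x, p, grad, eps, n_steps, inv_mass):
    x = x.copy()
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, grad
        p = p + (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return x, p, lp, grad


def _find_initial_step(logp_grad, x0, lp0, grad0, inv_mass, rng):
    """Crude bracketing: double/halve eps until one leapfrog step has
    acceptance probability crossing 0.5 (Hoffman & Gelman's heuristic)."""
    eps = 0.1
    p = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p * p)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x0, p, grad0, eps, 1, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        x1, p1, lp1, _ = _leapfrog(logp_grad, x0, p, grad0, eps, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def sample_hmc(
    logp_grad: LogpGrad,
    initial_points: np.ndarray,
    n_iterations: int,
    warmup: int,
    seed: int,
    max_leapfrog: int = 32,
    target_accept: float = 0.8,
) -> HMCResult:
    """Run one HMC chain per row of ``initial_points``.

    ``n_iterations`` includes ``warmup``; only post-warmup draws are kept.
    Chains are seeded independently from ``seed`` and run sequentially.
    """
    initial_points = np.atleast_2d(np.asarray(initial_points, dtype=float))
    n_chains, dim = initial_points.shape
    n_kept = n_iterations - warmup
    if n_kept <= 0:
        raise ValueError("n_iterations must exceed warmup")
    draws = np.empty((n_chains, n_kept, dim))
    logps = np.empty((n_chains, n_kept))
    accept_rate = np.zeros(n_chains)
    step_sizes = np.zeros(n_chains)
    divergences = np.zeros(n_chains, dtype=int)

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        x = initial_points[c].copy()
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            raise ValueError("initial point has non-finite log density")
        inv_mass = np.ones(dim)

        # mass-matrix window: middle 50% of warmup
        win_lo, win_hi = int(0.25 * warmup), int(0.75 * warmup)
        window: list[np.ndarray] = []

        eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
        mu = np.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        adapt_start = 0
        accepts = 0.0

        for it in range(n_iterations):
            p = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h_curr = lp - 0.5 * np.sum(inv_mass * p * p)
            n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
            x_new, p_new, lp_new, grad_new = _leapfrog(
                logp_grad, x, p, grad, eps, n_steps, inv_mass
            )
            if np.isfinite(lp_new):
                h_new = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
                delta = h_new - h_curr
            else:
                delta = -np.inf
            if delta < -1000.0 or not np.isfinite(delta):
                alpha_prob = 0.0
                if it >= warmup:
                    divergences[c] += 1
            else:
                alpha_prob = min(1.0, float(np.exp(min(delta, 0.0))))
            if rng.random() < alpha_prob:
                x, lp, grad = x_new, lp_new, grad_new

            if it < warmup:
                m = it - adapt_start + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha_prob) / (m + t0)
                log_eps = mu - np.sqrt(m) / gamma * h_bar
                w = m ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if win_lo <= it < win_hi:
                    window.append(x.copy())
                if it == win_hi - 1 and len(window) > 10:
                    var = np.var(np.asarray(window), axis=0)
                    inv_mass = np.maximum(var, 1e-8)
                    # restart step-size adaptation for the new metric
                    eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar = 0.0, 0.0
                    adapt_start = it + 1
                if it == warmup - 1:
                    eps = float(np.exp(log_eps_bar))
                    # sanity probe: a chain can leave warmup with a step
                    # size tuned in a region it has since drifted out of;
                    # halve until short trajectories accept again
                    for _ in range(6):
                        acc = 0.0
                        for _ in range(5):
                            p_t = rng.standard_normal(dim) / np.sqrt(inv_mass)
                            h_t = lp - 0.5 * np.sum(inv_mass * p_t * p_t)
                            x_t, p_t2, lp_t, _ = _leapfrog(
                                logp_grad, x, p_t, grad, eps, 4, inv_mass
                            )
                            if np.isfinite(lp_t):
                                h_n = lp_t - 0.5 * np.sum(inv_mass * p_t2 * p_t2)
                                if np.isfinite(h_n):
                                    acc += min(1.0, np.exp(min(h_n - h_t, 0.0)))
                        if acc / 5.0 >= 0.5:
                            break
                        eps *= 0.5
            else:
                accepts += alpha_prob
                k = it - warmup
                draws[c, k] = x
                logps[c, k] = lp

        accept_rate[c] = accepts / n_kept
        step_sizes[c] = eps

    return HMCResult(
        draws=draws,
        accept_rate=accept_rate,
        step_size=step_sizes,
        divergences=divergences,
        logp=logps,
    )
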