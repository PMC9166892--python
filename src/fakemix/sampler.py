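"""Adaptive Hamiltonian Monte Carlo.

A compact, dependency-free HMC sampler used by :mod:`fakemix.estimation`:
leapfrog integration with a diagonal mass matrix, dual-averaging step-size
adaptation toward a target acceptance rate during warmup (Hoffman & Gelman
style), and a mid-warmup mass-matrix update from the empirical draw
variances.  Gradients are supplied analytically by the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np

logger = logging.getLogger(__name__)

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]

#: energy-error threshold beyond which a trajectory counts as divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    """Post-warmup draws and sampling statistics of one chain."""

    draws: np.ndarray                 # (n_kept, dim)
    accept_rate: float
    step_size: float
    divergences: int
    inv_mass: np.ndarray = field(repr=False, default=None)


class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance rate)."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.h_bar = 0.0
        self.log_eps_bar = math.log(eps0)
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return math.exp(log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def _leapfrog(logp_grad: LogpGrad, x: np.ndarray, p: np.ndarray, grad: np.ndarray,
              eps: float, n_steps: int, inv_mass: np.ndarray):
    """Standard leapfrog integration; returns final state and log density."""
    x, p = x.copy(), p.copy()
    p += 0.5 * eps * grad
    for step in range(n_steps):
        x += eps * inv_mass * p
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return x, p, logp, grad
        p += (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return x, p, logp, grad


def _find_initial_step_size(logp_grad: LogpGrad, x: np.ndarray, logp: float,
                            grad: np.ndarray, inv_mass: np.ndarray,
                            rng: np.random.Generator) -> float:
    """Double/halve until the one-step acceptance probability crosses 1/2."""
    eps = 0.1
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * float(p * inv_mass @ p)
    x1, p1, logp1, _ = _leapfrog(logp_grad, x, p, grad, eps, 1, inv_mass)
    h1 = logp1 - 0.5 * float(p1 * inv_mass @ p1) if np.isfinite(logp1) else -np.inf
    direction = 1 if (h1 - h0) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        x1, p1, logp1, _ = _leapfrog(logp_grad, x, p, grad, eps, 1, inv_mass)
        h1 = logp1 - 0.5 * float(p1 * inv_mass @ p1) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return max(eps, 1e-8)


def hmc_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_iterations: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    n_leapfrog: int = 16,
) -> ChainResult:
    """Run one HMC chain and return the post-warmup draws.

    Warmup schedule: dual averaging of the step size throughout; the
    diagonal mass matrix is replaced once, at 60% of warmup, by the
    regularized empirical variance of the preceding window's draws, after
    which step-size adaptation restarts.  The number of leapfrog steps is
    jittered uniformly in ``[n_leapfrog // 2, 3 * n_leapfrog // 2]`` to
    avoid resonances.
    """
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial position has non-finite log density")

    eps = _find_initial_step_size(logp_grad, x, logp, grad, inv_mass, rng)
    averager = _DualAveraging(eps, target_accept)
    mass_update_at = int(0.6 * n_warmup)
    window_draws = []

    kept = np.empty((n_iterations - n_warmup, dim))
    n_accept = 0
    n_divergent = 0
    lo = max(1, n_leapfrog // 2)
    hi = max(lo + 1, (3 * n_leapfrog) // 2 + 1)

    for it in range(n_iterations):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * float(p * inv_mass @ p)
        n_steps = int(rng.integers(lo, hi))
        x1, p1, logp1, grad1 = _leapfrog(logp_grad, x, p, grad, eps, n_steps, inv_mass)
        if np.isfinite(logp1):
            h1 = logp1 - 0.5 * float(p1 * inv_mass @ p1)
            delta = h1 - h0
            # count only post-warmup divergences (warmup transients are
            # expected while the step size is still being tuned)
            if delta < -DIVERGENCE_THRESHOLD and it >= n_warmup:
                n_divergent += 1
        else:
            # support boundary or overflow: plain rejection
            delta = -np.inf
        accept_prob = min(1.0, math.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        if rng.random() < accept_prob:
            x, logp, grad = x1, logp1, grad1
            if it >= n_warmup:
                n_accept += 1

        if it < n_warmup:
            eps = averager.update(accept_prob)
            if it >= mass_update_at // 3:
                window_draws.append(x.copy())
            if it == mass_update_at and len(window_draws) >= 10:
                var = np.var(np.asarray(window_draws), axis=0)
                n_w = len(window_draws)
                inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                inv_mass = np.clip(inv_mass, 1e-8, None)
                eps = averager.adapted
                averager = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = averager.adapted
        else:
            kept[it - n_warmup] = x

    n_kept = n_iterations - n_warmup
    result = ChainResult(
        draws=kept,
        accept_rate=n_accept / max(n_kept, 1),
        step_size=eps,
        divergences=n_divergent,
        inv_mass=inv_mass,
    )
    if n_divergent:
        logger.warning("HMC chain had %d divergent trajectories", n_divergent)
    return result
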