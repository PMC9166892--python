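"""The Faking Mixture model.

In a high-stakes administration a person either fakes a block — choosing a
rank order by its desirability — or responds honestly.  The observed
response probability is the two-component mixture

    P(X_jk = r) = Phi(theta_j + alpha_k) * P(X_k = r | fake)
                + (1 - Phi(theta_j + alpha_k)) * P(X_jk = r | honest),

where the faking rank-order probabilities are a softmax of unconstrained
block-level parameters beta_kr (first order fixed at 0 for identification),
theta_j is a person-level faking trait, and the block fakability alpha_k is
*derived* from the rank-order probabilities: the standard-normal quantile of
their sum of squared deviations from the mean.  Blocks where one rank order
is clearly preferable thus have high fakability; perfectly matched blocks
(uniform probabilities) have fakability -> -inf, clamped at a small floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri, softmax

from .errors import DataError, DomainError

__all__ = [
    "RankOrderParameters",
    "FakingTrait",
    "BlockFakability",
    "FAKABILITY_FLOOR_EPS",
    "faking_rank_probabilities",
    "block_fakability",
    "faking_probability",
    "mixture_probability",
    "log_likelihood",
]

#: floor applied to the sum-of-squares argument of the fakability quantile;
#: keeps alpha finite (~ -6.36) and gradients defined at uniform softmax output
FAKABILITY_FLOOR_EPS = 1e-10


@dataclass
class RankOrderParameters:
    """Unconstrained rank-order parameters ``beta``, shape ``(n_blocks, R)``.

    The first column (lexicographically first rank order) is the fixed-zero
    identification reference in every block.
    """

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise DomainError("rank-order parameters must be finite")
        if np.any(self.beta[:, 0] != 0.0):
            raise DomainError(
                "beta[:, 0] must be 0 (identification: first rank order is the "
                "reference); use RankOrderParameters.from_free or .identified"
            )

    @classmethod
    def from_free(cls, free: np.ndarray) -> "RankOrderParameters":
        """Build from the free entries, shape ``(n_blocks, R - 1)``."""
        free = np.atleast_2d(np.asarray(free, dtype=float))
        beta = np.concatenate([np.zeros((free.shape[0], 1)), free], axis=1)
        return cls(beta)

    @staticmethod
    def identify(beta: np.ndarray) -> np.ndarray:
        """Shift each row so the first entry is 0 (softmax-invariant)."""
        beta = np.atleast_2d(np.asarray(beta, dtype=float))
        return beta - beta[:, :1]

    @property
    def free(self) -> np.ndarray:
        return self.beta[:, 1:]

    @property
    def n_blocks(self) -> int:
        return self.beta.shape[0]

    @property
    def n_orders(self) -> int:
        return self.beta.shape[1]

    def probabilities(self) -> np.ndarray:
        """Softmax rank-order probabilities per block, shape ``(n_blocks, R)``."""
        return faking_rank_probabilities(self.beta)

    def fakability(self) -> np.ndarray:
        """Derived block fakabilities ``alpha_k``, shape ``(n_blocks,)``."""
        return block_fakability(self.probabilities())


@dataclass
class FakingTrait:
    """Person-level faking trait ``theta`` with its distribution parameters."""

    theta: np.ndarray
    mean: float = 0.0
    variance: float = 1.0

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if not self.variance > 0:
            raise DomainError(f"faking-trait variance must be > 0, got {self.variance}")


@dataclass
class BlockFakability:
    """Derived block fakabilities; kept as a named type for reporting."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))


def faking_rank_probabilities(beta: np.ndarray) -> np.ndarray:
    """Softmax of rank-order parameters along the last axis.

    ``P(X_k = r | fake) = exp(beta_kr) / sum_u exp(beta_ku)``; numerically
    stabilized by max subtraction, hence invariant to adding a constant to a
    block's row.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise DomainError("rank-order parameters must be finite")
    return softmax(beta, axis=-1)


def block_fakability(
    probs: np.ndarray, floor_eps: float = FAKABILITY_FLOOR_EPS
) -> np.ndarray | float:
    """Derived block fakability: normal quantile of the probability spread.

    ``alpha = ndtri( sum_r (P_r - mean(P))^2 )`` for each probability vector
    along the last axis.  The argument lies in ``[0, (R-1)/R]``; it is
    clamped below at ``floor_eps`` so the uniform vector maps to a finite
    floor (~ -6.36) rather than -inf.
    """
    probs = np.asarray(probs, dtype=float)
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise DomainError("rank-order probabilities must sum to 1 per block")
    dev = probs - probs.mean(axis=-1, keepdims=True)
    ss = np.square(dev).sum(axis=-1)
    alpha = ndtri(np.clip(ss, floor_eps, None))
    return float(alpha) if np.ndim(alpha) == 0 else alpha


def faking_probability(theta, alpha) -> np.ndarray | float:
    """Probit probability of faking, ``Phi(theta_j + alpha_k)`` (broadcasting)."""
    out = ndtr(np.asarray(theta, dtype=float) + np.asarray(alpha, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def mixture_probability(
    theta_j: float, beta_k: np.ndarray, honest_k: np.ndarray
) -> np.ndarray:
    """Full response-probability vector for one person-block.

    Convex combination of the faking softmax vector and the fixed honest
    vector, weighted by the faking probability ``Phi(theta_j + alpha_k)``
    with ``alpha_k`` derived from ``beta_k``.
    """
    honest_k = np.asarray(honest_k, dtype=float)
    if abs(float(honest_k.sum()) - 1.0) > 1e-6:
        raise DomainError("honest probabilities must sum to 1")
    p_fake = faking_rank_probabilities(np.asarray(beta_k, dtype=float))
    w = faking_probability(theta_j, block_fakability(p_fake))
    return w * p_fake + (1.0 - w) * honest_k


def log_likelihood(
    responses: np.ndarray,
    beta: RankOrderParameters | np.ndarray,
    theta: FakingTrait | np.ndarray,
    honest: np.ndarray,
) -> float:
    """Observed-data log likelihood of the Faking Mixture model.

    Parameters
    ----------
    responses
        ``(n_persons, n_blocks)`` canonical rank-order indices in ``1..R``.
    beta
        Rank-order parameters (``(n_blocks, R)`` with zero reference column).
    theta
        Faking-trait values, length ``n_persons``.
    honest
        Honest probabilities ``(n_persons, n_blocks, R)`` (or an
        :class:`~fakemix.thurstonian.HonestProbabilityArray`).

    The faking indicator is marginalized analytically; the mixture weight
    and components are recomputed from the parameters for every term.
    """
    beta_arr = beta.beta if isinstance(beta, RankOrderParameters) else np.asarray(beta)
    theta_arr = theta.theta if isinstance(theta, FakingTrait) else np.atleast_1d(theta)
    honest_arr = getattr(honest, "probs", honest)
    honest_arr = np.asarray(honest_arr, dtype=float)

    responses = np.asarray(responses)
    n, k = responses.shape
    r = honest_arr.shape[2]
    bad = (responses < 1) | (responses > r)
    if bad.any():
        j, b = next(zip(*np.nonzero(bad)))
        raise DataError(
            f"response index {responses[j, b]} for person {j} block {b} "
            f"outside 1..{r}"
        )

    p_fake = faking_rank_probabilities(beta_arr)           # (K, R)
    alpha = block_fakability(p_fake)                       # (K,)
    w = faking_probability(theta_arr[:, None], alpha[None, :])  # (N, K)

    ridx = responses - 1
    px = p_fake[np.arange(k)[None, :], ridx]               # (N, K)
    hx = np.take_along_axis(honest_arr, ridx[:, :, None], axis=2)[:, :, 0]
    lik = w * px + (1.0 - w) * hx
    return float(np.log(np.clip(lik, 1e-300, None)).sum())
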