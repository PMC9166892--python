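"""Honest-response engine: Thurstonian IRT rank-order probabilities.

Under Thurstone's law of comparative judgment each item has a latent
utility ``t_i = mu_i + lambda_i * eta_trait(i) + eps_i`` with independent
normal errors ``eps_i ~ N(0, psi_i^2)``; a respondent ranks the items of a
block by decreasing utility.  The probability of a rank order is therefore
a positive-orthant probability of the multivariate normal distribution of
successive utility differences: with the block's utilities and error
variances sorted by the rank order and ``A`` the successive-difference
contrast matrix,

    P(order) = P( A t > 0 ),   A t ~ N( A m,  A diag(psi^2) A^T ).

These probabilities form the honest (non-faking) component of the faking
mixture and are computed once, up front, from item and trait parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .design import BlockDesign, comparison_matrix, enumerate_rank_orders
from .errors import ConfigurationError, DomainError, NumericalError

__all__ = [
    "ContentTraits",
    "HonestProbabilityArray",
    "compute_utility_means",
    "honest_rank_probability",
    "honest_probability_table",
]

logger = logging.getLogger(__name__)

#: persons x traits matrix of latent content-trait scores
ContentTraits = np.ndarray

#: absolute accuracy target for the orthant integration
ORTHANT_ABS_TOL = 1e-6


@dataclass
class HonestProbabilityArray:
    """Per person-block probabilities of each rank order under honest responding.

    ``probs`` has shape ``(n_persons, n_blocks, R)`` where axis 2 follows the
    canonical lexicographic order indexing; rows are rescaled to sum to
    exactly 1 (mirroring the handling of numerical integration error).
    """

    probs: np.ndarray
    tolerance: float = ORTHANT_ABS_TOL

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise DomainError(
                f"honest probabilities must be (persons, blocks, R), got shape "
                f"{self.probs.shape}"
            )
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise DomainError("honest probabilities must lie in [0, 1]")

    @property
    def n_persons(self) -> int:
        return self.probs.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.probs.shape[1]

    @property
    def n_orders(self) -> int:
        return self.probs.shape[2]


def compute_utility_means(design: BlockDesign, traits: ContentTraits) -> np.ndarray:
    """Deterministic part of the utilities, ``mu_i + lambda_i * eta_j,trait(i)``.

    Returns a ``(n_persons, n_items)`` matrix in the design's item order.
    Errors are *not* added here; they enter through the covariance in
    :func:`honest_rank_probability` or as explicit draws in the simulator.
    """
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    trait_idx = design.trait_index.ravel()
    if trait_idx.max() >= traits.shape[1]:
        raise ConfigurationError(
            f"design references trait {trait_idx.max() + 1} but only "
            f"{traits.shape[1]} trait columns were supplied"
        )
    mu = design.intercepts.ravel()
    lam = design.loadings.ravel()
    return mu[None, :] + lam[None, :] * traits[:, trait_idx]


def _orthant_probability(mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """P(d > 0) for ``d ~ N(mean, cov)``, batched over rows of ``mean``.

    Uses the symmetry identity P(d > 0) = P(N(0, cov) <= mean) so a single
    scipy CDF call (deterministic Genz quasi-Monte-Carlo lattice) handles
    all rows.  Falls back to a randomized-QMC estimate with a logged error
    bound if scipy returns a non-finite value.
    """
    mean = np.atleast_2d(mean)
    dim = mean.shape[1]
    if dim == 1:
        return ndtr(mean[:, 0] / math.sqrt(float(cov[0, 0])))
    out = stats.multivariate_normal.cdf(
        mean, mean=np.zeros(dim), cov=cov, abseps=ORTHANT_ABS_TOL / 10, releps=0.0,
        maxpts=100_000 * dim,
    )
    out = np.atleast_1d(np.asarray(out, dtype=float))
    bad = ~np.isfinite(out)
    if bad.any():
        logger.warning(
            "orthant integration returned %d non-finite values; "
            "falling back to randomized QMC", int(bad.sum()),
        )
        for i in np.nonzero(bad)[0]:
            out[i] = _qmc_orthant(mean[i], cov)
    return np.clip(out, 0.0, 1.0)


def _qmc_orthant(mean: np.ndarray, cov: np.ndarray, n: int = 1 << 14) -> float:
    """Randomized quasi-Monte-Carlo orthant probability (fallback path)."""
    dim = len(mean)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(dim))
    estimates = []
    for seed in range(8):
        sob = stats.qmc.Sobol(dim, scramble=True, rng=np.random.default_rng(seed))
        u = sob.random(n)
        z = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
        d = mean[None, :] + z @ chol.T
        estimates.append(float(np.mean(np.all(d > 0, axis=1))))
    est = float(np.mean(estimates))
    err = float(np.std(estimates) / math.sqrt(len(estimates)))
    logger.warning("QMC orthant fallback: estimate %.6g, error bound ~%.2g", est, err)
    if not np.isfinite(est):
        raise NumericalError("orthant probability could not be computed")
    return est


def honest_rank_probability(
    mean_utilities: Sequence[float],
    error_variances: Sequence[float],
    order: Sequence[int],
) -> float:
    """Probability of one rank order for one person-block.

    Parameters
    ----------
    mean_utilities, error_variances
        Length-``B`` vectors aligned to the block's items (item label ``i``
        is position ``i - 1``).
    order
        Rank order as 1-based item labels in descending preference.
    """
    m = np.asarray(mean_utilities, dtype=float)
    psi2 = np.asarray(error_variances, dtype=float)
    if np.any(psi2 <= 0):
        raise DomainError(f"error variances must be positive, got {psi2}")
    b = len(m)
    table = enumerate_rank_orders(b)
    table.index(order)  # validates the permutation
    idx = np.asarray(order, dtype=np.int64) - 1
    a = comparison_matrix(b)
    d_mean = a @ m[idx]
    d_cov = a @ np.diag(psi2[idx]) @ a.T
    return float(_orthant_probability(d_mean[None, :], d_cov)[0])


def honest_probability_table(
    design: BlockDesign,
    traits: ContentTraits,
    warn_tolerance: float = 1e-4,
) -> HonestProbabilityArray:
    """Honest rank-order probabilities for every person, block and order.

    Per person-block the ``R`` orthant probabilities are computed and then
    rescaled to sum to exactly 1 (dividing by their sum), absorbing the
    numerical integration error.  Cells whose pre-rescaling sum deviates
    from 1 by more than ``warn_tolerance`` are logged.
    """
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    n = traits.shape[0]
    k, b = design.n_blocks, design.block_size
    table = enumerate_rank_orders(b)
    r = table.n_orders
    a = comparison_matrix(b)
    means = compute_utility_means(design, traits).reshape(n, k, b)

    probs = np.empty((n, k, r))
    for ki in range(k):
        psi2 = design.error_variances[ki]
        for ri, order in enumerate(table.orders):
            idx = np.asarray(order, dtype=np.int64) - 1
            d_mean = means[:, ki, idx] @ a.T
            d_cov = a @ np.diag(psi2[idx]) @ a.T
            probs[:, ki, ri] = _orthant_probability(d_mean, d_cov)

    sums = probs.sum(axis=2)
    off = np.abs(sums - 1.0) > warn_tolerance
    if off.any():
        cells = list(zip(*np.nonzero(off)))
        logger.warning(
            "%d person-block cells had pre-rescaling probability sums deviating "
            "from 1 by more than %g (first few: %s)",
            len(cells), warn_tolerance, cells[:5],
        )
    probs /= sums[:, :, None]
    return HonestProbabilityArray(probs=probs)
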