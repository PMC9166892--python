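"""Synthetic-data generator for the parameter-recovery study conditions.

Emulates the generating design of the recovery simulation: correlated Big
Five content traits, uniform Thurstonian item parameters with mixed keying
and an identifiability (no within-block linear dependency) check, honest
responses by ranking latent utilities, and high-stakes responses from the
faking mixture under a fully crossed 2 (fakability) x 3 (faking-trait mean)
x 3 (faking-trait variance) condition grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .design import BlockDesign, enumerate_rank_orders
from .errors import ConfigurationError, InvalidDesignError
from .mixture import (
    FakingTrait,
    RankOrderParameters,
    block_fakability,
    faking_probability,
    faking_rank_probabilities,
)

__all__ = [
    "SimulationCondition",
    "condition_grid",
    "big_five_correlations",
    "default_trait_assignment",
    "draw_content_traits",
    "draw_item_parameters",
    "simulate_honest_responses",
    "draw_faking_parameters",
    "simulate_faking_responses",
    "max_rank_probability_sample",
    "mean_faking_probability",
    "FAKABILITY_BETA_RANGE",
]

logger = logging.getLogger(__name__)

#: half-width of the uniform distribution the rank-order parameters are
#: drawn from, per fakability level
FAKABILITY_BETA_RANGE = {"low": 2.0, "high": 4.0}

_DESIGN_MEANS = (0.0, 1.0, 2.0)
_DESIGN_VARIANCES = (0.2, 0.5, 1.0)

#: default generating scale: 500 persons, 20 blocks of 3 items, 5 traits
DEFAULT_N_PERSONS = 500
DEFAULT_N_BLOCKS = 20
DEFAULT_BLOCK_SIZE = 3
DEFAULT_N_TRAITS = 5


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the crossed recovery-study design."""

    fakability: str
    theta_mean: float
    theta_variance: float

    def __post_init__(self) -> None:
        if self.fakability not in FAKABILITY_BETA_RANGE:
            raise ConfigurationError(
                f"fakability must be one of {sorted(FAKABILITY_BETA_RANGE)}, "
                f"got {self.fakability!r}"
            )
        if self.theta_variance <= 0:
            raise ConfigurationError("faking-trait variance must be > 0")
        if not self.on_design:
            logger.info("off-design condition %s", self)

    @property
    def on_design(self) -> bool:
        """Whether the levels belong to the crossed study grid."""
        return (
            any(math.isclose(self.theta_mean, m) for m in _DESIGN_MEANS)
            and any(math.isclose(self.theta_variance, v) for v in _DESIGN_VARIANCES)
        )

    @property
    def label(self) -> str:
        return f"{self.fakability}_m{self.theta_mean:g}_v{self.theta_variance:g}"


def condition_grid() -> List[SimulationCondition]:
    """The 18 fully crossed conditions, fakability-major then mean then variance."""
    return [
        SimulationCondition(f, m, v)
        for f in ("low", "high")
        for m in _DESIGN_MEANS
        for v in _DESIGN_VARIANCES
    ]


def big_five_correlations() -> np.ndarray:
    """Meta-analytic Big Five intercorrelations (order N, E, O, A, C)."""
    upper = {
        (0, 1): -0.36, (0, 2): -0.17, (0, 3): -0.36, (0, 4): -0.43,
        (1, 2): 0.43, (1, 3): 0.26, (1, 4): 0.29,
        (2, 3): 0.21, (2, 4): 0.20,
        (3, 4): 0.43,
    }
    r = np.eye(5)
    for (i, j), v in upper.items():
        r[i, j] = r[j, i] = v
    return r


def draw_content_traits(
    n_persons: int,
    corr: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw content traits from ``MVN(0, corr)`` (unit variances).

    ``corr`` defaults to the Big Five meta-analytic matrix.  Raises
    :class:`ConfigurationError` if ``corr`` is not symmetric positive
    definite.
    """
    rng = np.random.default_rng(rng)
    corr = big_five_correlations() if corr is None else np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ConfigurationError("trait correlation matrix must be symmetric with unit diagonal")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("trait correlation matrix is not positive definite") from exc
    z = rng.standard_normal((n_persons, corr.shape[0]))
    return z @ chol.T


def default_trait_assignment(
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_traits: int = DEFAULT_N_TRAITS,
) -> np.ndarray:
    """Balanced 0-based trait assignment, distinct traits within each block.

    Items cycle through the traits in order, so with 20 blocks of 3 items
    and 5 traits each trait is measured by 12 items.
    """
    if block_size > n_traits:
        raise InvalidDesignError(
            "block size cannot exceed the number of traits (items within a "
            "block must measure distinct traits)"
        )
    flat = np.arange(n_blocks * block_size) % n_traits
    return flat.reshape(n_blocks, block_size)


def _has_linear_dependency(loadings: np.ndarray, tol: float = 1e-3) -> bool:
    """Heuristic identifiability check for one block's loading vector.

    Rejects blocks whose loadings are equal in magnitude (within ``tol``) or
    proportional: any repeated pairwise |loading| ratio marks a dependency.
    """
    mag = np.abs(loadings)
    b = len(mag)
    ratios = []
    for i in range(b):
        for j in range(b):
            if i != j:
                ratios.append(mag[i] / mag[j])
    ratios = np.sort(np.asarray(ratios))
    if np.any(np.abs(ratios - 1.0) < tol):  # two loadings of equal size
        return True
    return bool(np.any(np.diff(ratios) < tol))  # proportional pattern


def draw_item_parameters(
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_traits: int = DEFAULT_N_TRAITS,
    trait_assignment: np.ndarray | None = None,
    keying_plan: Sequence[Sequence[int]] | None = None,
    rng: np.random.Generator | int | None = None,
    max_redraws: int = 1000,
) -> BlockDesign:
    """Draw standardized Thurstonian item parameters for a questionnaire.

    Intercepts are uniform on (-1, 1); loading magnitudes uniform on
    (.65, .95) with signs from the keying plan; error variances are set to
    ``1 - loading**2`` (standardized utilities).  Each block's loadings are
    redrawn until the linear-dependency heuristic passes.

    ``keying_plan`` gives the loading signs per block.  The default flips
    one item per block (uniformly chosen), so 2 of the 3 pairwise
    comparisons in a triplet are between differently keyed items — the
    closest realizable value to half.
    """
    rng = np.random.default_rng(rng)
    if trait_assignment is None:
        trait_assignment = default_trait_assignment(n_blocks, block_size, n_traits)
    trait_assignment = np.asarray(trait_assignment)
    if keying_plan is None:
        signs = np.ones((n_blocks, block_size))
        flip = rng.integers(0, block_size, size=n_blocks)
        signs[np.arange(n_blocks), flip] = -1.0
    else:
        signs = np.asarray(keying_plan, dtype=float)
        if signs.shape != (n_blocks, block_size) or not np.all(np.abs(signs) == 1):
            raise ConfigurationError("keying plan must be +-1 with shape (n_blocks, block_size)")

    intercepts = rng.uniform(-1.0, 1.0, size=(n_blocks, block_size))
    loadings = np.empty((n_blocks, block_size))
    for k in range(n_blocks):
        for attempt in range(max_redraws):
            lam = rng.uniform(0.65, 0.95, size=block_size)
            if not _has_linear_dependency(lam):
                loadings[k] = lam * signs[k]
                break
        else:
            raise InvalidDesignError(
                f"block {k}: exceeded {max_redraws} redraws without an "
                "identifiable loading pattern; try a different keying plan"
            )
    error_variances = 1.0 - loadings**2
    return BlockDesign.from_arrays(intercepts, loadings, error_variances, trait_assignment)


def simulate_honest_responses(
    design: BlockDesign,
    traits: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate honest rank-order responses by ranking noisy utilities.

    Independent normal errors with the items' error variances are added to
    the mean utilities; items are ranked within block by decreasing utility
    (exact ties, possible only at degenerate parameters, break by stable
    item order).  Returns ``(n_persons, n_blocks)`` canonical order indices
    in ``1..R``.
    """
    from .thurstonian import compute_utility_means

    rng = np.random.default_rng(rng)
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    n = traits.shape[0]
    k, b = design.n_blocks, design.block_size
    means = compute_utility_means(design, traits).reshape(n, k, b)
    eps = rng.standard_normal((n, k, b)) * np.sqrt(design.error_variances)[None, :, :]
    utilities = means + eps
    # descending stable sort -> item labels by preference
    ranked = np.argsort(-utilities, axis=2, kind="stable") + 1
    table = enumerate_rank_orders(b)
    lookup = {order: i + 1 for i, order in enumerate(table.orders)}
    out = np.empty((n, k), dtype=np.int64)
    flat = ranked.reshape(-1, b)
    codes = np.array([lookup[tuple(row)] for row in map(tuple, flat)], dtype=np.int64)
    out[:] = codes.reshape(n, k)
    return out


def draw_faking_parameters(
    condition: SimulationCondition,
    n_blocks: int = DEFAULT_N_BLOCKS,
    n_orders: int = 6,
    n_persons: int = DEFAULT_N_PERSONS,
    rng: np.random.Generator | int | None = None,
) -> tuple[RankOrderParameters, FakingTrait]:
    """Draw generating faking parameters for one condition.

    All ``R`` rank-order parameters per block are uniform on ``(-c, c)``
    with ``c = 2`` (low fakability) or ``4`` (high); softmax shift
    invariance makes the generated probabilities independent of the
    estimation-side zero-reference constraint, so the returned ``beta`` is
    shifted to the identified scale (first column 0) for bookkeeping.
    The faking trait is normal with the condition's mean and variance,
    independent of the content traits.
    """
    rng = np.random.default_rng(rng)
    c = FAKABILITY_BETA_RANGE[condition.fakability]
    raw = rng.uniform(-c, c, size=(n_blocks, n_orders))
    beta = RankOrderParameters(RankOrderParameters.identify(raw))
    theta = rng.normal(
        condition.theta_mean, math.sqrt(condition.theta_variance), size=n_persons
    )
    trait = FakingTrait(
        theta=theta, mean=condition.theta_mean, variance=condition.theta_variance
    )
    return beta, trait


def simulate_faking_responses(
    honest_responses: np.ndarray,
    beta: RankOrderParameters,
    theta: FakingTrait | np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate high-stakes responses under the faking mixture.

    Per person-block a faking indicator is drawn with probability
    ``Phi(theta_j + alpha_k)``; faked cells replace the honest order by a
    draw from the block's softmax rank-order distribution.
    """
    rng = np.random.default_rng(rng)
    honest_responses = np.asarray(honest_responses)
    theta_arr = theta.theta if isinstance(theta, FakingTrait) else np.atleast_1d(theta)
    n, k = honest_responses.shape
    probs = beta.probabilities()                      # (K, R)
    alpha = block_fakability(probs)                   # (K,)
    p_fake = faking_probability(theta_arr[:, None], alpha[None, :])  # (N, K)
    fakes = rng.random((n, k)) < p_fake
    # categorical draws from each block's rank-order distribution
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n, k))
    drawn = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2) + 1
    return np.where(fakes, drawn, honest_responses)


# ---------------------------------------------------------------------------
# design constants: Monte-Carlo characterizations of the condition grid
# ---------------------------------------------------------------------------

def max_rank_probability_sample(
    fakability: str,
    n_blocks: int = 100_000,
    n_orders: int = 6,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-block maximum softmax probability over many simulated blocks.

    Characterizes a fakability level: for low fakability 90% of the maxima
    fall roughly in [.3, .6] (mean ~.4), for high fakability in [.4, .9]
    (mean ~.6).
    """
    rng = np.random.default_rng(rng)
    c = FAKABILITY_BETA_RANGE[fakability]
    beta = rng.uniform(-c, c, size=(n_blocks, n_orders))
    return faking_rank_probabilities(beta).max(axis=1)


def mean_faking_probability(
    fakability: str,
    theta_mean: float,
    n_blocks: int = 100_000,
    n_orders: int = 6,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean faking probability across blocks for the average respondent.

    Averages ``Phi(theta_mean + alpha)`` over the fakability level's
    block-fakability distribution (Monte Carlo over simulated blocks); the
    probit is evaluated at the faking-trait mean.  Spans ~.15 (low
    fakability, mean 0) to ~.90 (high fakability, mean 2) across the design.
    """
    rng = np.random.default_rng(rng)
    c = FAKABILITY_BETA_RANGE[fakability]
    beta = rng.uniform(-c, c, size=(n_blocks, n_orders))
    alpha = block_fakability(faking_rank_probabilities(beta))
    return float(np.mean(faking_probability(theta_mean, alpha)))
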