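"""Questionnaire structure: blocks, items, and rank-order bookkeeping.

A multidimensional forced-choice (MFC) questionnaire consists of blocks of
``B`` items; a response to a block is one of the ``R = B!`` rank orders of
its items.  Throughout the package a rank order is written as a tuple of
1-based item labels in *descending* preference, so ``(3, 1, 2)`` means item
3 was ranked highest.  Rank orders carry a canonical 1-based index given by
their lexicographic position (``(1, 2, 3)`` -> 1, ..., ``(3, 2, 1)`` -> 6
for ``B = 3``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidDesignError

__all__ = [
    "ItemParameters",
    "PermutationTable",
    "BlockDesign",
    "enumerate_rank_orders",
    "comparison_matrix",
]

#: column order of the on-disk item-parameter table
ITEM_COLUMNS = ["item_id", "block_id", "trait", "intercept", "loading", "error_variance"]


@dataclass(frozen=True)
class ItemParameters:
    """Thurstonian parameters of a single item.

    The latent utility of person *j* on this item is
    ``t = intercept + loading * eta[trait_index] + eps`` with
    ``eps ~ N(0, error_variance)``.  For standardized utilities (the
    simulator default) ``error_variance = 1 - loading**2``.

    ``trait_index`` is 1-based, matching the on-disk table.
    """

    intercept: float
    loading: float
    error_variance: float
    trait_index: int

    def __post_init__(self) -> None:
        if not self.error_variance > 0:
            raise InvalidDesignError(
                f"error_variance must be positive, got {self.error_variance!r}"
            )
        if self.trait_index < 1:
            raise ConfigurationError(f"trait_index must be >= 1, got {self.trait_index}")


@dataclass(frozen=True)
class PermutationTable:
    """All ``R = B!`` rank orders of a block, in lexicographic order.

    ``orders[i]`` is the rank order with canonical (1-based) index ``i + 1``.
    The first entry is always the identity permutation.
    """

    block_size: int
    orders: Tuple[Tuple[int, ...], ...]
    _index: dict = field(repr=False, hash=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {order: i + 1 for i, order in enumerate(self.orders)}
        )

    @property
    def n_orders(self) -> int:
        return len(self.orders)

    def index(self, order: Sequence[int]) -> int:
        """Canonical 1-based index of ``order`` (descending-preference labels)."""
        try:
            return self._index[tuple(int(x) for x in order)]
        except KeyError:
            raise InvalidDesignError(
                f"{tuple(order)} is not a permutation of 1..{self.block_size}"
            ) from None

    def order(self, index: int) -> Tuple[int, ...]:
        """Rank order for a canonical 1-based index."""
        if not 1 <= index <= self.n_orders:
            raise InvalidDesignError(
                f"order index {index} outside 1..{self.n_orders}"
            )
        return self.orders[index - 1]

    def as_array(self) -> np.ndarray:
        """All orders as an ``(R, B)`` integer array of 1-based item labels."""
        return np.asarray(self.orders, dtype=np.int64)


@lru_cache(maxsize=None)
def enumerate_rank_orders(block_size: int) -> PermutationTable:
    """Enumerate the ``R = B!`` rank orders of a block of ``block_size`` items.

    Orders are tuples of 1-based item labels in descending preference,
    listed lexicographically; e.g. for ``B = 3``:
    1-2-3, 1-3-2, 2-1-3, 2-3-1, 3-1-2, 3-2-1.
    """
    if block_size < 2:
        raise InvalidDesignError(f"block size must be >= 2, got {block_size}")
    orders = tuple(itertools.permutations(range(1, block_size + 1)))
    return PermutationTable(block_size=block_size, orders=orders)


def comparison_matrix(block_size: int) -> np.ndarray:
    """Successive-difference contrast matrix ``A`` of shape ``(B - 1, B)``.

    Row ``b`` has 1 at column ``b`` and -1 at column ``b + 1``: applied to a
    utility vector sorted by a rank order, ``A t`` collects the differences
    that are all positive exactly when the rank order holds.
    """
    if block_size < 2:
        raise InvalidDesignError(f"block size must be >= 2, got {block_size}")
    a = np.zeros((block_size - 1, block_size))
    idx = np.arange(block_size - 1)
    a[idx, idx] = 1.0
    a[idx, idx + 1] = -1.0
    return a


class BlockDesign:
    """An MFC questionnaire: items with Thurstonian parameters grouped in blocks.

    Parameters
    ----------
    items
        Table with columns ``item_id, block_id, trait, intercept, loading,
        error_variance`` (``trait`` is 1-based).  Every item belongs to
        exactly one block and all blocks share the same size ``B >= 2``.
    """

    def __init__(self, items: pd.DataFrame):
        missing = [c for c in ITEM_COLUMNS if c not in items.columns]
        if missing:
            raise InvalidDesignError(f"item table is missing columns {missing}")
        items = items.loc[:, ITEM_COLUMNS].copy()
        if items["item_id"].duplicated().any():
            dupes = items.loc[items["item_id"].duplicated(), "item_id"].tolist()
            raise InvalidDesignError(
                f"items assigned to more than one row/block: {dupes}"
            )
        sizes = items.groupby("block_id", sort=True).size()
        if sizes.nunique() != 1:
            raise InvalidDesignError(
                f"all blocks must share one block size, got sizes {sorted(set(sizes))}"
            )
        block_size = int(sizes.iloc[0])
        if block_size < 2:
            raise InvalidDesignError(f"block size must be >= 2, got {block_size}")
        if (items["error_variance"] <= 0).any():
            raise InvalidDesignError("error variances must be positive")
        if (items["trait"] < 1).any():
            raise ConfigurationError("trait indices must be >= 1")

        self.items = items.sort_values(["block_id", "item_id"], kind="stable").reset_index(
            drop=True
        )
        self.block_ids = list(self.items["block_id"].drop_duplicates())
        self.block_size = block_size
        self.n_blocks = len(self.block_ids)
        self.n_traits = int(self.items["trait"].max())

        shape = (self.n_blocks, self.block_size)
        self.intercepts = self.items["intercept"].to_numpy().reshape(shape)
        self.loadings = self.items["loading"].to_numpy().reshape(shape)
        self.error_variances = self.items["error_variance"].to_numpy().reshape(shape)
        #: 0-based trait index per (block, item-in-block)
        self.trait_index = self.items["trait"].to_numpy(dtype=np.int64).reshape(shape) - 1

    @property
    def n_items(self) -> int:
        return self.n_blocks * self.block_size

    @property
    def n_orders(self) -> int:
        return math.factorial(self.block_size)

    @property
    def permutations(self) -> PermutationTable:
        return enumerate_rank_orders(self.block_size)

    @classmethod
    def from_arrays(
        cls,
        intercepts: np.ndarray,
        loadings: np.ndarray,
        error_variances: np.ndarray,
        trait_index: np.ndarray,
        block_ids: Iterable | None = None,
    ) -> "BlockDesign":
        """Build a design from ``(n_blocks, block_size)`` arrays.

        ``trait_index`` is 0-based here (converted to the 1-based table
        convention internally).
        """
        intercepts = np.asarray(intercepts, dtype=float)
        loadings = np.asarray(loadings, dtype=float)
        error_variances = np.asarray(error_variances, dtype=float)
        trait_index = np.asarray(trait_index, dtype=np.int64)
        k, b = intercepts.shape
        block_ids = list(block_ids) if block_ids is not None else list(range(1, k + 1))
        rows = []
        item = 1
        for ki in range(k):
            for bi in range(b):
                rows.append(
                    {
                        "item_id": item,
                        "block_id": block_ids[ki],
                        "trait": int(trait_index[ki, bi]) + 1,
                        "intercept": float(intercepts[ki, bi]),
                        "loading": float(loadings[ki, bi]),
                        "error_variance": float(error_variances[ki, bi]),
                    }
                )
                item += 1
        return cls(pd.DataFrame(rows))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BlockDesign(n_blocks={self.n_blocks}, block_size={self.block_size}, "
            f"n_traits={self.n_traits})"
        )
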