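"""File formats, configuration and run manifests.

All tabular artifacts are comma-separated UTF-8 text with a header row and
"." decimals.  Rank-order responses are stored either as canonical 1-based
lexicographic indices or as permutation tokens like ``3-1-2`` (item labels
by descending preference; en-dashes are normalized to hyphens on read).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ITEM_COLUMNS, BlockDesign, enumerate_rank_orders
from .errors import ConfigurationError, ParseError
from .thurstonian import HonestProbabilityArray

__all__ = [
    "parse_rank_order",
    "format_rank_order",
    "read_design",
    "write_design",
    "read_responses",
    "write_responses",
    "read_honest_probabilities",
    "write_honest_probabilities",
    "read_beta",
    "write_beta",
    "read_theta",
    "write_theta",
    "RunConfig",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_DASHES = re.compile(r"[-–—]")


def parse_rank_order(token, block_size: int, context: str = "") -> int:
    """Parse a response cell into the canonical 1-based order index.

    Accepts either an integer index in ``1..B!`` or a dash-separated
    permutation of the item labels (``"3-1-2"``; en-dash tolerated).
    """
    table = enumerate_rank_orders(block_size)
    where = f" ({context})" if context else ""
    s = str(token).strip()
    parts = [p for p in _DASHES.split(s) if p != ""]
    try:
        if len(parts) <= 1:
            idx = int(s)
            if not 1 <= idx <= table.n_orders:
                raise ParseError(
                    f"order index {idx} outside 1..{table.n_orders}{where}"
                )
            return idx
        labels = tuple(int(p) for p in parts)
    except ParseError:
        raise
    except ValueError:
        raise ParseError(f"cannot parse rank-order token {token!r}{where}") from None
    if sorted(labels) != list(range(1, block_size + 1)):
        raise ParseError(
            f"token {token!r} is not a permutation of 1..{block_size}{where}"
        )
    return table.index(labels)


def format_rank_order(index: int, block_size: int, style: str = "index") -> str:
    """Inverse of :func:`parse_rank_order` (``style``: "index" or "token")."""
    table = enumerate_rank_orders(block_size)
    if style == "index":
        table.order(index)  # validate
        return str(index)
    if style == "token":
        return "-".join(str(i) for i in table.order(index))
    raise ConfigurationError(f"unknown rank-order style {style!r}")


# -- item parameters ---------------------------------------------------------

def read_design(path) -> BlockDesign:
    return BlockDesign(pd.read_csv(path))


def write_design(design: BlockDesign, path) -> None:
    design.items.loc[:, ITEM_COLUMNS].to_csv(path, index=False)


# -- responses ----------------------------------------------------------------

def read_responses(path, block_size: int) -> np.ndarray:
    """Read a response matrix (rows: persons, columns: blocks after person_id)."""
    df = pd.read_csv(path, dtype=str)
    cols = [c for c in df.columns if c != "person_id"]
    out = np.empty((len(df), len(cols)), dtype=np.int64)
    for j, col in enumerate(cols):
        for i, token in enumerate(df[col]):
            out[i, j] = parse_rank_order(
                token, block_size, context=f"row {i + 2}, column {col!r}"
            )
    return out


def write_responses(responses: np.ndarray, path, block_size: int,
                    style: str = "index") -> None:
    responses = np.asarray(responses)
    data = {"person_id": np.arange(1, responses.shape[0] + 1)}
    for j in range(responses.shape[1]):
        data[f"block{j + 1}"] = [
            format_rank_order(int(v), block_size, style) for v in responses[:, j]
        ]
    pd.DataFrame(data).to_csv(path, index=False)


# -- honest probabilities ------------------------------------------------------

def read_honest_probabilities(path) -> HonestProbabilityArray:
    """Read the long-format table (person_id, block_id, order_index, prob)."""
    df = pd.read_csv(path)
    persons = np.sort(df["person_id"].unique())
    blocks = np.sort(df["block_id"].unique())
    r = int(df["order_index"].max())
    pidx = {p: i for i, p in enumerate(persons)}
    bidx = {b: i for i, b in enumerate(blocks)}
    probs = np.zeros((len(persons), len(blocks), r))
    probs[
        df["person_id"].map(pidx).to_numpy(),
        df["block_id"].map(bidx).to_numpy(),
        df["order_index"].to_numpy() - 1,
    ] = df["prob"].to_numpy()
    probs /= probs.sum(axis=2, keepdims=True)
    return HonestProbabilityArray(probs=probs)


def write_honest_probabilities(honest: HonestProbabilityArray, path) -> None:
    n, k, r = honest.probs.shape
    p, b, o = np.meshgrid(np.arange(n), np.arange(k), np.arange(r), indexing="ij")
    pd.DataFrame({
        "person_id": p.ravel() + 1,
        "block_id": b.ravel() + 1,
        "order_index": o.ravel() + 1,
        "prob": honest.probs.ravel(),
    }).to_csv(path, index=False)


# -- parameter tables ----------------------------------------------------------

def read_beta(path) -> np.ndarray:
    df = pd.read_csv(path)
    k = int(df["block_id"].max())
    r = int(df["order_index"].max())
    beta = np.zeros((k, r))
    beta[df["block_id"] - 1, df["order_index"] - 1] = df["beta"]
    return beta


def write_beta(beta: np.ndarray, path) -> None:
    beta = np.atleast_2d(beta)
    k, r = beta.shape
    b, o = np.meshgrid(np.arange(k), np.arange(r), indexing="ij")
    pd.DataFrame({
        "block_id": b.ravel() + 1,
        "order_index": o.ravel() + 1,
        "beta": beta.ravel(),
    }).to_csv(path, index=False)


def read_theta(path) -> np.ndarray:
    return pd.read_csv(path)["theta"].to_numpy(dtype=float)


def write_theta(theta: np.ndarray, path) -> None:
    theta = np.atleast_1d(theta)
    pd.DataFrame({
        "person_id": np.arange(1, theta.size + 1), "theta": theta,
    }).to_csv(path, index=False)


# -- run configuration ---------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML on disk).

    ``seed`` is mandatory; every referenced input path must resolve at
    validation time.
    """

    seed: int
    out_dir: str = "fakemix_out"
    # design / simulation
    n_persons: int = 500
    n_blocks: int = 20
    block_size: int = 3
    n_traits: int = 5
    fakability: str = "low"
    theta_mean: float = 1.0
    theta_variance: float = 0.5
    # estimation
    n_chains: int = 3
    n_iterations: int = 3500
    n_warmup: int = 750
    fix_var_theta: Optional[float] = None
    fix_var_beta: Optional[float] = None
    # recovery
    n_replications: int = 2
    # input paths (stage-dependent)
    responses: Optional[str] = None
    responses_b: Optional[str] = None
    honest: Optional[str] = None
    honest_b: Optional[str] = None
    shared_blocks: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in raw or raw["seed"] is None:
            raise ConfigurationError("config must provide a seed")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("responses", "responses_b", "honest", "honest_b"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if self.n_warmup >= self.n_iterations:
            raise ConfigurationError("n_warmup must be < n_iterations")


def write_manifest(out_dir, config: dict, artifacts: dict, status: str = "ok") -> Path:
    """Write a JSON manifest (inputs, seeds, versions) next to the artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "status": status,
        "config": config,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "versions": {
            "fakemix": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path
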