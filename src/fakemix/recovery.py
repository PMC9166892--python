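"""Parameter-recovery study harness.

Runs simulate -> fit -> evaluate replications over the crossed condition
grid, computes the recovery metrics (coverage of 95% posterior intervals,
correlation between true values and posterior medians, mean bias and SD of
bias) per parameter family, and decomposes each metric's variance over the
design factors with a descriptive balanced-ANOVA sums-of-squares
decomposition (no F tests).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FakemixError
from .estimation import (
    PosteriorResult,
    PriorConfig,
    SamplerConfig,
    fit_faking_mixture,
)
from .mixture import FakingTrait, RankOrderParameters
from .simulate import (
    SimulationCondition,
    condition_grid,
    draw_content_traits,
    draw_faking_parameters,
    draw_item_parameters,
    simulate_faking_responses,
    simulate_honest_responses,
)
from .thurstonian import honest_probability_table

__all__ = [
    "TrueParameters",
    "RecoveryMetrics",
    "RecoveryReport",
    "compute_recovery",
    "variance_explained",
    "run_recovery_study",
]

logger = logging.getLogger(__name__)

FACTORS = ["fakability", "theta_mean", "theta_var"]
METRICS = ["coverage", "correlation", "mean_bias", "sd_bias"]


@dataclass
class TrueParameters:
    """Generating parameter values of one replication (identified scale)."""

    beta: RankOrderParameters
    theta: FakingTrait
    condition: SimulationCondition

    @property
    def var_beta(self) -> float:
        """Realized variance of the identified free rank-order parameters.

        The generating model draws beta from a uniform, so no normal
        variance parameter exists; the sample variance of the true free
        entries is the natural comparator for the Var(beta) hyperparameter.
        """
        return float(np.var(self.beta.free, ddof=1))


@dataclass
class RecoveryMetrics:
    """Recovery metrics per parameter family for one fitted replication.

    ``biases`` keeps the raw per-parameter biases (median - true) so a
    study can pool them across replications instead of averaging
    replication-level SDs.
    """

    table: pd.DataFrame
    biases: dict = field(default_factory=dict)

    def value(self, family: str, metric: str) -> float:
        row = self.table[self.table["family"] == family]
        if row.empty:
            raise DataError(f"unknown parameter family {family!r}")
        return float(row.iloc[0][metric])


def _metrics_for(true: np.ndarray, draws: np.ndarray) -> dict:
    """Coverage/correlation/bias for one family.

    ``true`` is length-m; ``draws`` is (samples, m).
    """
    true = np.atleast_1d(np.asarray(true, dtype=float))
    med = np.median(draws, axis=0)
    # order-statistic methods keep infinite draws (improper intervals) exact
    lo = np.quantile(draws, 0.025, axis=0, method="lower")
    hi = np.quantile(draws, 0.975, axis=0, method="higher")
    bias = med - true
    m = true.size
    if m > 1 and np.std(true) > 0 and np.std(med) > 0:
        corr = float(np.corrcoef(true, med)[0, 1])
    else:
        corr = float("nan")
    return {
        "coverage": float(np.mean((true >= lo) & (true <= hi))),
        "correlation": corr,
        "mean_bias": float(np.mean(bias)),
        "sd_bias": float(np.std(bias, ddof=1)) if m > 1 else float("nan"),
        "n_parameters": m,
    }


def compute_recovery(true: TrueParameters, result: PosteriorResult) -> RecoveryMetrics:
    """Compare generating values with the posterior, per parameter family.

    Families: the main parameters (``theta``, free ``beta``), the
    hyperparameters (``m_theta``, ``var_theta``, ``var_beta``) and the
    derived parameters (``alpha``, ``rank_probs``).  Derived true values
    are recomputed from the true ``beta`` with the model operations.
    """
    kb = result.model.n_param_blocks
    r = result.model.n_orders
    if true.beta.n_blocks != kb or true.beta.n_orders != r:
        raise DataError(
            f"family beta misaligned: true {true.beta.beta.shape} vs "
            f"posterior ({kb}, {r})"
        )
    if true.theta.theta.size != result.model.n_persons_total:
        raise DataError(
            f"family theta misaligned: true {true.theta.theta.size} vs "
            f"posterior {result.model.n_persons_total}"
        )

    flat = result.flat
    rows = []
    families = {
        "theta": (true.theta.theta, flat(result.theta)),
        "beta": (true.beta.free.ravel(),
                 flat(result.beta)[:, :, 1:].reshape(-1, kb * (r - 1))),
        "m_theta": (true.condition.theta_mean, flat(result.m_theta)[:, None]),
        "var_theta": (true.condition.theta_variance, flat(result.var_theta)[:, None]),
        "var_beta": (true.var_beta, flat(result.var_beta)[:, None]),
        "alpha": (true.beta.fakability(), flat(result.alpha)),
        "rank_probs": (true.beta.probabilities().ravel(),
                       flat(result.rank_probs).reshape(-1, kb * r)),
    }
    biases = {}
    for family, (tv, draws) in families.items():
        rows.append({"family": family, **_metrics_for(tv, draws)})
        biases[family] = np.median(draws, axis=0) - np.atleast_1d(tv)
    return RecoveryMetrics(table=pd.DataFrame(rows), biases=biases)


def variance_explained(
    metrics: pd.DataFrame, value_col: str = "value"
) -> pd.Series:
    """Descriptive balanced-ANOVA variance decomposition of one metric.

    ``metrics`` holds one row per replication per design cell with columns
    ``fakability, theta_mean, theta_var`` and ``value_col``.  Returns the
    percentage of total sum of squares attributed to each main effect,
    two-way and three-way interaction of the three design factors, plus the
    residual; components sum to 100 (up to rounding).  Requires a complete
    crossed grid with at least 2 replications per cell.
    """
    df = metrics.dropna(subset=[value_col])
    levels = {f: sorted(df[f].unique()) for f in FACTORS}
    cells = list(itertools.product(*levels.values()))
    counts = df.groupby(FACTORS, sort=True).size()
    missing = [c for c in cells if c not in counts.index]
    if missing:
        raise DataError(f"empty design cells: {missing}")
    if (counts < 2).any():
        raise DataError("need at least 2 replications per condition")

    y = df[value_col].to_numpy(dtype=float)
    grand = y.mean()
    total_ss = float(np.sum((y - grand) ** 2))
    if total_ss <= 1e-12 * max(float(np.sum(y**2)), 1.0):
        # constant metric: everything is residual
        keys = [":".join(c) for k in range(1, 4)
                for c in itertools.combinations(FACTORS, k)]
        return pd.Series({**{k: 0.0 for k in keys}, "residual": 100.0})

    def effect(cols: Sequence[str]) -> float:
        """SS of the |cols|-way effect, subtracting all nested lower effects."""
        means = df.groupby(list(cols), sort=True)[value_col].mean()
        sizes = df.groupby(list(cols), sort=True).size()
        dev = means - grand
        for k in range(1, len(cols)):
            for sub in itertools.combinations(cols, k):
                sub_eff = _effects_cache[sub]
                idx = means.index.to_frame()[list(sub)]
                key = pd.MultiIndex.from_frame(idx) if len(sub) > 1 else idx.iloc[:, 0]
                dev = dev - sub_eff.reindex(key).to_numpy()
        _effects_cache[tuple(cols)] = dev
        return float((sizes * dev**2).sum())

    _effects_cache: dict = {}
    out = {}
    model_ss = 0.0
    for k in range(1, 4):
        for cols in itertools.combinations(FACTORS, k):
            ss = effect(cols)
            out[":".join(cols)] = ss
            model_ss += ss
    out["residual"] = total_ss - model_ss
    return pd.Series({k: 100.0 * v / total_ss for k, v in out.items()})


@dataclass
class RecoveryReport:
    """Aggregated outcome of a recovery study."""

    metrics: pd.DataFrame                      # replication-level long table
    condition_summary: pd.DataFrame            # mean/SD per condition x family
    variance: Optional[pd.DataFrame]           # % variance explained, or None
    failures: List[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "metrics": self.metrics.to_dict(orient="records"),
            "condition_summary": self.condition_summary.to_dict(orient="records"),
            "variance_explained": (
                self.variance.reset_index().to_dict(orient="records")
                if self.variance is not None else None
            ),
            "failures": self.failures,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    def to_text(self) -> str:
        lines = ["Recovery study", "=" * 14, ""]
        lines.append(f"conditions: {self.config.get('n_conditions')}  "
                     f"replications: {self.config.get('n_replications')}  "
                     f"failures: {len(self.failures)}")
        lines.append("")
        lines.append("Condition means (coverage / correlation / mean bias / SD bias):")
        lines.append(self.condition_summary.to_string(index=False,
                                                      float_format="%.3f"))
        if self.variance is not None:
            lines.append("")
            lines.append("Variance explained (% of total SS):")
            lines.append(self.variance.to_string(float_format="%.1f"))
        return "\n".join(lines)


def _is_complete_grid(conditions: Sequence[SimulationCondition]) -> bool:
    f = sorted({c.fakability for c in conditions})
    m = sorted({c.theta_mean for c in conditions})
    v = sorted({c.theta_variance for c in conditions})
    combos = {(c.fakability, c.theta_mean, c.theta_variance) for c in conditions}
    return len(combos) == len(f) * len(m) * len(v) and min(len(f), len(m), len(v)) > 1


def run_recovery_study(
    conditions: Optional[Sequence[SimulationCondition]] = None,
    n_replications: int = 2,
    n_persons: int = 100,
    n_blocks: int = 10,
    block_size: int = 3,
    n_traits: int = 5,
    priors: Optional[PriorConfig] = None,
    sampler: Optional[SamplerConfig] = None,
    seed: int | None = 0,
    sd_bias_pooling: str = "per_replication",
) -> RecoveryReport:
    """Simulate, fit and score replications across design conditions.

    The defaults are a reduced profile (100 persons, 10 blocks, reduced
    sampler budget) suitable for desk-scale runs; pass 500 persons,
    20 blocks and the simulation sampler preset for the full-scale design.
    Individual replication failures are logged and excluded, with the count
    reported.  All randomness derives from ``seed`` via spawned child
    seeds, so a report regenerates bit-identically from its config.

    ``sd_bias_pooling`` controls the condition-level SD-of-bias summary:
    ``"per_replication"`` (default) averages the within-replication SDs,
    ``"pooled"`` computes one SD over all biases of a condition.
    """
    if sd_bias_pooling not in ("per_replication", "pooled"):
        raise DataError(f"unknown sd_bias_pooling {sd_bias_pooling!r}")
    conditions = list(conditions) if conditions is not None else condition_grid()
    sampler = sampler or SamplerConfig.reduced()
    priors = priors or PriorConfig()
    n_runs = len(conditions) * n_replications
    children = np.random.SeedSequence(seed).spawn(n_runs)

    rows = []
    pooled_biases: dict = {}
    failures: List[dict] = []
    run = 0
    for cond in conditions:
        for rep in range(n_replications):
            child = children[run]
            run += 1
            try:
                rng = np.random.default_rng(child)
                design = draw_item_parameters(
                    n_blocks=n_blocks, block_size=block_size, n_traits=n_traits,
                    rng=rng,
                )
                traits = draw_content_traits(n_persons, rng=rng)
                honest_resp = simulate_honest_responses(design, traits, rng=rng)
                honest = honest_probability_table(design, traits)
                beta_true, theta_true = draw_faking_parameters(
                    cond, n_blocks=n_blocks, n_orders=design.n_orders,
                    n_persons=n_persons, rng=rng,
                )
                faked = simulate_faking_responses(honest_resp, beta_true,
                                                  theta_true, rng=rng)
                result = fit_faking_mixture(
                    faked, honest, priors=priors, sampler=sampler, seed=rng,
                )
                rec = compute_recovery(
                    TrueParameters(beta_true, theta_true, cond), result
                )
            except (FakemixError, np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("replication failed (%s rep %d): %s",
                               cond.label, rep, exc)
                failures.append({"condition": cond.label, "replication": rep,
                                 "error": str(exc)})
                continue
            for family, b in rec.biases.items():
                key = (cond.fakability, cond.theta_mean, cond.theta_variance, family)
                pooled_biases.setdefault(key, []).append(np.atleast_1d(b))
            for _, row in rec.table.iterrows():
                rows.append({
                    "fakability": cond.fakability,
                    "theta_mean": cond.theta_mean,
                    "theta_var": cond.theta_variance,
                    "replication": rep,
                    "family": row["family"],
                    **{m: row[m] for m in METRICS},
                })

    metrics = pd.DataFrame(rows)
    if metrics.empty:
        raise FakemixError("all replications failed; no recovery metrics")

    condition_summary = (
        metrics.groupby(FACTORS + ["family"], sort=True)[METRICS]
        .agg(["mean", "std"])
        .reset_index()
    )
    condition_summary.columns = [
        c[0] if not c[1] else f"{c[0]}_{c[1]}" for c in condition_summary.columns
    ]
    if sd_bias_pooling == "pooled":
        pooled = {
            key: float(np.std(np.concatenate(arrs), ddof=1))
            if sum(a.size for a in arrs) > 1 else float("nan")
            for key, arrs in pooled_biases.items()
        }
        keys = condition_summary[FACTORS + ["family"]].apply(tuple, axis=1)
        condition_summary["sd_bias_mean"] = keys.map(pooled)

    variance = None
    if n_replications >= 2 and _is_complete_grid(conditions) and not failures:
        vrows = {}
        for family in metrics["family"].unique():
            sub = metrics[metrics["family"] == family]
            for metric in METRICS:
                if sub[metric].isna().any():
                    continue
                vrows[(family, metric)] = variance_explained(
                    sub.rename(columns={metric: "value"}), "value"
                )
        if vrows:
            variance = pd.DataFrame(vrows).T
            variance.index.names = ["family", "metric"]

    config = {
        "seed": seed,
        "n_conditions": len(conditions),
        "conditions": [c.label for c in conditions],
        "n_replications": n_replications,
        "n_persons": n_persons,
        "n_blocks": n_blocks,
        "block_size": block_size,
        "n_traits": n_traits,
        "sampler": vars(sampler),
        "priors": vars(priors),
        "sd_bias_pooling": sd_bias_pooling,
        "reduced_scale": n_persons < 500 or n_blocks < 20,
        "n_failures": len(failures),
    }
    return RecoveryReport(
        metrics=metrics, condition_summary=condition_summary,
        variance=variance, failures=failures, config=config,
    )
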