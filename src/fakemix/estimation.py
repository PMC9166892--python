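"""Bayesian estimation of the Faking Mixture model.

The model is fit in the two-step spirit: honest-response probabilities are
computed (or supplied) first and held fixed; the mixture parameters are
then sampled from their posterior given high-stakes responses.  The faking
indicator is marginalized analytically, so the posterior is differentiable
and sampled with Hamiltonian Monte Carlo (:mod:`fakemix.sampler`) using
analytic gradients.

Priors (hyperpriors reduce prior sensitivity):

    beta_kr   ~ N(0, SD(beta)),  beta_k1 = 0 fixed
    theta_j   ~ N(M(theta), SD(theta))
    M(theta)  ~ N(1, 2)
    Var(theta)~ Inverse-Gamma(1.5, 1)
    Var(beta) ~ Normal(5, 10) truncated to (0, 15)

The second argument of each normal is a standard deviation.  Either
variance can instead be fixed (the empirical preset fixes Var(theta)=0.25
and Var(beta)=4, leaving only M(theta) with a hyperprior).  Internally the
faking trait is sampled non-centered and the variances on the log scale
with Jacobian corrections; reported draws are on the natural scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri, softmax

from .errors import ConfigurationError, DataError
from .mixture import FAKABILITY_FLOOR_EPS
from .sampler import ChainResult, hmc_chain
from .thurstonian import HonestProbabilityArray

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "PosteriorResult",
    "ConvergenceReport",
    "fit_faking_mixture",
    "fit_multigroup",
    "convergence_check",
    "summarize_posterior",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class PriorConfig:
    """Priors and hyperpriors of the faking mixture.

    ``hyper_*`` tuples are the distribution parameters listed in the module
    docstring; ``fix_var_theta`` / ``fix_var_beta``, when given, replace the
    corresponding hyperprior by a fixed value.
    """

    hyper_mean_theta: tuple = (1.0, 2.0)          # normal(mean, sd)
    hyper_var_theta: tuple = (1.5, 1.0)           # inverse-gamma(shape, scale)
    hyper_var_beta: tuple = (5.0, 10.0, 0.0, 15.0)  # trunc-normal(mean, sd, lo, hi)
    fix_var_theta: Optional[float] = None
    fix_var_beta: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("fix_var_theta", "fix_var_beta"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")

    @classmethod
    def empirical(cls) -> "PriorConfig":
        """Fixed variances used for empirical data: Var(theta)=.25, Var(beta)=4."""
        return cls(fix_var_theta=0.25, fix_var_beta=4.0)


@dataclass
class SamplerConfig:
    """MCMC settings.  Defaults mirror the recovery-simulation settings."""

    n_chains: int = 3
    n_iterations: int = 3500
    n_warmup: int = 750
    target_accept: float = 0.8
    n_leapfrog: int = 16
    jitter: float = 0.1

    def __post_init__(self) -> None:
        if not self.n_warmup < self.n_iterations:
            raise ConfigurationError("n_warmup must be smaller than n_iterations")

    @classmethod
    def simulation(cls) -> "SamplerConfig":
        return cls(n_chains=3, n_iterations=3500, n_warmup=750)

    @classmethod
    def empirical(cls) -> "SamplerConfig":
        return cls(n_chains=6, n_iterations=5000, n_warmup=2500)

    @classmethod
    def reduced(cls) -> "SamplerConfig":
        """Small budget for smoke tests and scaled-down studies."""
        return cls(n_chains=1, n_iterations=800, n_warmup=400)


@dataclass
class _Group:
    """Pre-gathered data of one respondent group."""

    resp0: np.ndarray        # (N, K) 0-based order indices
    honest_x: np.ndarray     # (N, K) honest probability of the observed order
    theta_slice: slice       # slice into the global theta vector


def _as_honest_array(honest) -> np.ndarray:
    arr = honest.probs if isinstance(honest, HonestProbabilityArray) else np.asarray(honest)
    if arr.ndim != 3:
        raise DataError("honest probabilities must have shape (persons, blocks, R)")
    return np.asarray(arr, dtype=float)


def _validate_responses(responses: np.ndarray, honest: np.ndarray) -> np.ndarray:
    responses = np.asarray(responses)
    if responses.shape != honest.shape[:2]:
        raise DataError(
            f"responses {responses.shape} do not match honest probabilities "
            f"{honest.shape[:2]}"
        )
    r = honest.shape[2]
    bad = (responses < 1) | (responses > r)
    if bad.any():
        j, k = next(zip(*np.nonzero(bad)))
        raise DataError(
            f"response index {responses[j, k]} for person {j} block {k} outside 1..{r}"
        )
    return responses.astype(np.int64) - 1


class FakingMixtureModel:
    """Joint posterior over (possibly multi-group) faking-mixture parameters.

    Rank-order parameter rows live in a global table of ``n_param_blocks``
    blocks; each group maps its questionnaire blocks into that table
    (identical maps share parameters).  The parameter vector is

        [beta_free (n_param_blocks x (R-1)), theta_tilde (N_total),
         M(theta), log Var(theta)?, log Var(beta)?]

    with the optional coordinates absent when the variance is fixed.
    """

    def __init__(
        self,
        groups: List[_Group],
        beta_maps: List[np.ndarray],
        n_param_blocks: int,
        n_orders: int,
        priors: PriorConfig,
    ):
        self.groups = groups
        self.beta_maps = [np.asarray(m, dtype=np.int64) for m in beta_maps]
        self.n_param_blocks = n_param_blocks
        self.n_orders = n_orders
        self.priors = priors
        self.n_persons_total = sum(g.resp0.shape[0] for g in groups)
        self._nb = n_param_blocks * (n_orders - 1)
        self.sample_var_theta = priors.fix_var_theta is None
        self.sample_var_beta = priors.fix_var_beta is None
        self.dim = (
            self._nb
            + self.n_persons_total
            + 1
            + int(self.sample_var_theta)
            + int(self.sample_var_beta)
        )

    # -- packing ------------------------------------------------------------

    def unpack(self, x: np.ndarray):
        nb, n = self._nb, self.n_persons_total
        beta_free = x[:nb].reshape(self.n_param_blocks, self.n_orders - 1)
        theta_t = x[nb:nb + n]
        pos = nb + n
        m_theta = x[pos]
        pos += 1
        if self.sample_var_theta:
            w_theta = x[pos]
            pos += 1
        else:
            w_theta = math.log(self.priors.fix_var_theta)
        if self.sample_var_beta:
            w_beta = x[pos]
        else:
            w_beta = math.log(self.priors.fix_var_beta)
        return beta_free, theta_t, m_theta, w_theta, w_beta

    # -- densities ----------------------------------------------------------

    def _likelihood_and_grads(self, beta_free: np.ndarray, theta: np.ndarray):
        """Log likelihood plus gradients w.r.t. the global beta table and theta."""
        r = self.n_orders
        beta_full = np.concatenate(
            [np.zeros((self.n_param_blocks, 1)), beta_free], axis=1
        )
        p = softmax(beta_full, axis=1)                       # (KB, R)
        dev = p - 1.0 / r
        ss = np.square(dev).sum(axis=1)
        clamped = ss < FAKABILITY_FLOOR_EPS
        alpha = ndtri(np.clip(ss, FAKABILITY_FLOOR_EPS, None))
        phi_alpha = np.exp(-0.5 * alpha**2) / math.sqrt(2 * math.pi)

        loglik = 0.0
        g_p = np.zeros_like(p)
        g_theta = np.empty_like(theta)
        for g, bmap in zip(self.groups, self.beta_maps):
            th = theta[g.theta_slice]
            p_g = p[bmap]                                    # (K, R)
            alpha_g = alpha[bmap]
            eta = th[:, None] + alpha_g[None, :]             # (N, K)
            w = ndtr(eta)
            k_g = g.resp0.shape[1]
            px = p_g[np.arange(k_g)[None, :], g.resp0]       # (N, K)
            lik = w * px + (1.0 - w) * g.honest_x
            lik = np.clip(lik, 1e-300, None)
            loglik += float(np.log(lik).sum())

            phi_eta = np.exp(-0.5 * eta**2) / math.sqrt(2 * math.pi)
            d = (px - g.honest_x) / lik
            ge = phi_eta * d                                 # dloglik/deta (N, K)
            g_theta[g.theta_slice] = ge.sum(axis=1)
            g_alpha = ge.sum(axis=0)                         # (K,)

            # direct dloglik/dP at the observed order
            wt = w / lik                                     # (N, K)
            gp_g = np.zeros((k_g, r))
            for k in range(k_g):
                gp_g[k] = np.bincount(g.resp0[:, k], weights=wt[:, k], minlength=r)
            # chain through alpha
            dalpha = np.where(clamped[bmap, None], 0.0,
                              2.0 * dev[bmap] / phi_alpha[bmap, None])
            gp_g += g_alpha[:, None] * dalpha
            np.add.at(g_p, bmap, gp_g)

        inner = (g_p * p).sum(axis=1, keepdims=True)
        g_beta_full = p * (g_p - inner)
        return loglik, g_beta_full[:, 1:], g_theta, alpha, p

    def logp_grad(self, x: np.ndarray):
        """Internal (sampling-scale) log density and gradient."""
        pr = self.priors
        beta_free, theta_t, m_theta, w_theta, w_beta = self.unpack(x)
        if abs(w_theta) > 40 or abs(w_beta) > 40:  # far outside any prior mass
            return -np.inf, np.zeros_like(x)
        v_theta, v_beta = math.exp(w_theta), math.exp(w_beta)
        if self.sample_var_beta:
            lo, hi = pr.hyper_var_beta[2], pr.hyper_var_beta[3]
            if not lo < v_beta < hi:
                return -np.inf, np.zeros_like(x)
        sd_theta = math.sqrt(v_theta)
        theta = m_theta + sd_theta * theta_t

        loglik, g_beta, g_theta, _, _ = self._likelihood_and_grads(beta_free, theta)

        nb = self._nb
        n = self.n_persons_total
        m_mu, m_sd = pr.hyper_mean_theta

        logp = loglik
        logp += -0.5 * float(np.square(beta_free).sum()) / v_beta \
            - 0.5 * nb * (math.log(v_beta) + _LOG2PI)
        logp += -0.5 * float(np.square(theta_t).sum()) - 0.5 * n * _LOG2PI
        logp += -0.5 * ((m_theta - m_mu) / m_sd) ** 2 - math.log(m_sd) - 0.5 * _LOG2PI

        g = np.empty_like(x)
        g_beta = g_beta - beta_free / v_beta
        g[:nb] = g_beta.ravel()
        g[nb:nb + n] = g_theta * sd_theta - theta_t
        pos = nb + n
        g[pos] = g_theta.sum() - (m_theta - m_mu) / m_sd**2
        pos += 1
        if self.sample_var_theta:
            a, b = pr.hyper_var_theta
            logp += (-(a + 1.0) * w_theta - b / v_theta
                     + a * math.log(b) - math.lgamma(a)) + w_theta
            g[pos] = (float((g_theta * theta_t).sum()) * sd_theta * 0.5
                      - a + b / v_theta)
            pos += 1
        if self.sample_var_beta:
            mu_b, sd_b, lo, hi = pr.hyper_var_beta
            z = stats.norm.cdf((hi - mu_b) / sd_b) - stats.norm.cdf((lo - mu_b) / sd_b)
            logp += (-0.5 * ((v_beta - mu_b) / sd_b) ** 2 - math.log(sd_b)
                     - 0.5 * _LOG2PI - math.log(z)) + w_beta
            g[pos] = (0.5 * float(np.square(beta_free).sum()) / v_beta - 0.5 * nb
                      - (v_beta - mu_b) / sd_b**2 * v_beta + 1.0)
        return logp, g

    def log_density(
        self,
        beta_free: np.ndarray,
        theta: np.ndarray,
        m_theta: float,
        var_theta: float | None = None,
        var_beta: float | None = None,
    ) -> float:
        """Natural-scale log posterior density (up to nothing: fully normalized
        priors), i.e. the mixture log likelihood plus all log prior terms.

        Variances default to their fixed values when the prior fixes them.
        """
        pr = self.priors
        v_theta = pr.fix_var_theta if var_theta is None else var_theta
        v_beta = pr.fix_var_beta if var_beta is None else var_beta
        if v_theta is None or v_beta is None:
            raise ConfigurationError("variance value required when not fixed")
        beta_free = np.asarray(beta_free, dtype=float)
        theta = np.asarray(theta, dtype=float)
        sd_theta = math.sqrt(v_theta)
        theta_t = (theta - m_theta) / sd_theta
        x = np.concatenate([
            beta_free.ravel(), theta_t, [m_theta],
            [math.log(v_theta)] if self.sample_var_theta else [],
            [math.log(v_beta)] if self.sample_var_beta else [],
        ])
        internal, _ = self.logp_grad(x)
        # undo the non-centering and log-scale changes of variables
        out = internal - theta.size * math.log(sd_theta)
        if self.sample_var_theta:
            out -= math.log(v_theta)
        if self.sample_var_beta:
            out -= math.log(v_beta)
        return float(out)

    # -- initialization -----------------------------------------------------

    def initial_position(self, rng: np.random.Generator, jitter: float) -> np.ndarray:
        x = np.zeros(self.dim)
        pos = self._nb + self.n_persons_total
        x[pos] = self.priors.hyper_mean_theta[0]
        pos += 1
        if self.sample_var_theta:
            a, b = self.priors.hyper_var_theta
            x[pos] = math.log(float(stats.invgamma(a, scale=b).median()))
            pos += 1
        if self.sample_var_beta:
            mu_b, sd_b, lo, hi = self.priors.hyper_var_beta
            tn = stats.truncnorm((lo - mu_b) / sd_b, (hi - mu_b) / sd_b,
                                 loc=mu_b, scale=sd_b)
            x[pos] = math.log(float(tn.median()))
        if jitter > 0:
            x = x + jitter * rng.standard_normal(self.dim)
        return x


@dataclass
class ConvergenceReport:
    """Outcome of the R-hat / effective-sample-size screen."""

    passed: bool
    flagged: pd.DataFrame
    max_rhat: float
    min_ess_ratio: float
    notes: str = ""


@dataclass
class PosteriorResult:
    """Posterior draws, derived quantities and sampling diagnostics.

    Draw arrays are indexed ``(chain, draw, ...)``.  ``beta`` carries the
    fixed zero reference column; ``alpha`` and ``rank_probs`` are derived
    per draw from ``beta`` (never from summarized parameters).
    """

    beta: np.ndarray                     # (C, D, KB, R)
    theta: np.ndarray                    # (C, D, N_total)
    m_theta: np.ndarray                  # (C, D)
    var_theta: np.ndarray                # (C, D)
    var_beta: np.ndarray                 # (C, D)
    alpha: np.ndarray                    # (C, D, KB)
    rank_probs: np.ndarray               # (C, D, KB, R)
    model: FakingMixtureModel = field(repr=False)
    chain_stats: List[ChainResult] = field(repr=False, default_factory=list)
    group_labels: Sequence[str] = ("group0",)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Collapse chain and draw axes."""
        return arr.reshape(-1, *arr.shape[2:])

    def group_alpha(self, group: int = 0) -> np.ndarray:
        """Per-draw block fakabilities of one group, ``(C, D, K_group)``."""
        return self.alpha[:, :, self.model.beta_maps[group]]

    def alpha_difference(self, other_group: int = 1, base_group: int = 0) -> np.ndarray:
        """Per-draw alpha differences (other - base) for blocks not shared."""
        map_a = self.model.beta_maps[base_group]
        map_b = self.model.beta_maps[other_group]
        diff_blocks = np.nonzero(map_a != map_b)[0]
        return self.alpha[:, :, map_b[diff_blocks]] - self.alpha[:, :, map_a[diff_blocks]]

    def faking_probability_medians(self, group: int = 0) -> np.ndarray:
        """Posterior-median faking probability per person-block, ``(N, K)``."""
        g = self.model.groups[group]
        theta = self.flat(self.theta)[:, g.theta_slice]      # (S, N)
        alpha = self.flat(self.group_alpha(group))           # (S, K)
        n, k = g.resp0.shape
        out = np.empty((n, k))
        for ki in range(k):
            out[:, ki] = np.median(ndtr(theta + alpha[:, ki][:, None]), axis=0)
        return out

    def to_inference_data(self):
        """Export the main parameters to an :class:`arviz.InferenceData`."""
        import arviz as az

        data = {
            "beta_free": self.beta[:, :, :, 1:],
            "theta": self.theta,
            "m_theta": self.m_theta,
            "alpha": self.alpha,
        }
        if self.model.sample_var_theta:
            data["var_theta"] = self.var_theta
        if self.model.sample_var_beta:
            data["var_beta"] = self.var_beta
        return az.from_dict(posterior=data)


def _central_interval(draws: np.ndarray, level: float = 0.95):
    lo = (1 - level) / 2
    return np.quantile(draws, [0.5, lo, 1 - lo], axis=0)


def _build_model(
    responses_list, honest_list, beta_maps, n_param_blocks, priors
) -> FakingMixtureModel:
    groups = []
    offset = 0
    r = None
    for resp, honest in zip(responses_list, honest_list):
        arr = _as_honest_array(honest)
        if r is None:
            r = arr.shape[2]
        elif arr.shape[2] != r:
            raise ConfigurationError("groups must share the number of rank orders R")
        resp0 = _validate_responses(resp, arr)
        hx = np.take_along_axis(arr, resp0[:, :, None], axis=2)[:, :, 0]
        n = resp0.shape[0]
        groups.append(_Group(resp0=resp0, honest_x=hx,
                             theta_slice=slice(offset, offset + n)))
        offset += n
    return FakingMixtureModel(groups, beta_maps, n_param_blocks, r, priors)


def _run_chains(model: FakingMixtureModel, sampler: SamplerConfig,
                rng: np.random.Generator) -> List[ChainResult]:
    chains = []
    for c in range(sampler.n_chains):
        chain_rng = np.random.default_rng(rng.integers(2**31))
        x0 = model.initial_position(chain_rng, sampler.jitter)
        chains.append(
            hmc_chain(
                model.logp_grad, x0,
                n_iterations=sampler.n_iterations,
                n_warmup=sampler.n_warmup,
                rng=chain_rng,
                target_accept=sampler.target_accept,
                n_leapfrog=sampler.n_leapfrog,
            )
        )
        logger.info(
            "chain %d: accept %.2f, step %.3g, %d divergences",
            c, chains[-1].accept_rate, chains[-1].step_size, chains[-1].divergences,
        )
    return chains


def _result_from_chains(model: FakingMixtureModel, chains: List[ChainResult],
                        group_labels) -> PosteriorResult:
    kb, r = model.n_param_blocks, model.n_orders
    n = model.n_persons_total
    nb = model._nb
    draws = np.stack([c.draws for c in chains])              # (C, D, dim)
    c_, d_ = draws.shape[:2]
    beta_free = draws[:, :, :nb].reshape(c_, d_, kb, r - 1)
    beta = np.concatenate([np.zeros((c_, d_, kb, 1)), beta_free], axis=3)
    theta_t = draws[:, :, nb:nb + n]
    pos = nb + n
    m_theta = draws[:, :, pos]
    pos += 1
    if model.sample_var_theta:
        var_theta = np.exp(draws[:, :, pos])
        pos += 1
    else:
        var_theta = np.full((c_, d_), model.priors.fix_var_theta)
    if model.sample_var_beta:
        var_beta = np.exp(draws[:, :, pos])
    else:
        var_beta = np.full((c_, d_), model.priors.fix_var_beta)
    theta = m_theta[:, :, None] + np.sqrt(var_theta)[:, :, None] * theta_t

    rank_probs = softmax(beta, axis=3)
    dev = rank_probs - 1.0 / r
    ss = np.square(dev).sum(axis=3)
    alpha = ndtri(np.clip(ss, FAKABILITY_FLOOR_EPS, None))

    return PosteriorResult(
        beta=beta, theta=theta, m_theta=m_theta, var_theta=var_theta,
        var_beta=var_beta, alpha=alpha, rank_probs=rank_probs,
        model=model, chain_stats=chains, group_labels=tuple(group_labels),
    )


def fit_faking_mixture(
    responses: np.ndarray,
    honest: HonestProbabilityArray | np.ndarray,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> PosteriorResult:
    """Fit the Faking Mixture model to one group's high-stakes responses.

    Parameters
    ----------
    responses
        ``(n_persons, n_blocks)`` canonical rank-order indices in ``1..R``.
    honest
        Honest-response probabilities (fixed mixture component),
        ``(n_persons, n_blocks, R)``.
    priors, sampler
        Prior and MCMC settings; defaults are the recovery-simulation
        settings (3 chains x 3500 iterations, 750 warmup).
    seed
        Seed or generator driving chain initialization and sampling.
    """
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    arr = _as_honest_array(honest)
    k = arr.shape[1]
    model = _build_model([responses], [arr], [np.arange(k)], k, priors)
    rng = np.random.default_rng(seed)
    chains = _run_chains(model, sampler, rng)
    return _result_from_chains(model, chains, ["group0"])


def fit_multigroup(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    honest_a: HonestProbabilityArray | np.ndarray,
    honest_b: HonestProbabilityArray | np.ndarray,
    shared_blocks: Sequence[int],
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> PosteriorResult:
    """Joint two-group fit with rank-order parameters shared on common blocks.

    ``shared_blocks`` lists the 0-based block positions whose items are
    identical in the two questionnaire versions; those blocks share one set
    of rank-order parameters, all other blocks get separate parameters per
    group.  Each group keeps its own faking-trait vector; hyperparameters
    are shared.  Per-draw fakability differences for the non-shared blocks
    are available via :meth:`PosteriorResult.alpha_difference`.
    """
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    arr_a, arr_b = _as_honest_array(honest_a), _as_honest_array(honest_b)
    k = arr_a.shape[1]
    if arr_b.shape[1] != k:
        raise ConfigurationError("both groups must have the same number of blocks")
    shared = sorted(set(int(s) for s in shared_blocks))
    if shared and (shared[0] < 0 or shared[-1] >= k):
        raise ConfigurationError(f"shared block index outside 0..{k - 1}")
    separate = [b for b in range(k) if b not in shared]

    map_a = np.empty(k, dtype=np.int64)
    map_b = np.empty(k, dtype=np.int64)
    for pos, b in enumerate(shared):
        map_a[b] = map_b[b] = pos
    for pos, b in enumerate(separate):
        map_a[b] = len(shared) + pos
        map_b[b] = len(shared) + len(separate) + pos
    n_param_blocks = len(shared) + 2 * len(separate)

    model = _build_model(
        [responses_a, responses_b], [arr_a, arr_b], [map_a, map_b],
        n_param_blocks, priors,
    )
    rng = np.random.default_rng(seed)
    chains = _run_chains(model, sampler, rng)
    return _result_from_chains(model, chains, ["groupA", "groupB"])


def convergence_check(
    result: PosteriorResult,
    rhat_threshold: float = 1.01,
    ess_ratio_threshold: float = 0.001,
) -> ConvergenceReport:
    """Screen the posterior draws with split-R-hat and effective sample size.

    A parameter fails when its split-chain scale reduction is >= 1.01
    (strict inequality passes) or its ESS divided by the total number of
    draws is <= 0.001.
    """
    import arviz as az

    notes = ""
    if result.n_chains < 2:
        notes = "single chain: R-hat is within-chain (split) only; diagnostics limited"
        logger.warning(notes)
    idata = result.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    total = result.n_chains * result.n_draws

    rows = []
    for var in rhat.data_vars:
        rv = np.asarray(rhat[var]).ravel()
        ev = np.asarray(ess[var]).ravel() / total
        for i, (r_, e_) in enumerate(zip(rv, ev)):
            if (np.isfinite(r_) and r_ >= rhat_threshold) or e_ <= ess_ratio_threshold:
                rows.append({"parameter": f"{var}[{i}]", "rhat": float(r_),
                             "ess_ratio": float(e_)})
    flagged = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_ratio"])
    rhat_vals = np.concatenate([np.asarray(rhat[v]).ravel() for v in rhat.data_vars])
    ess_vals = np.concatenate([np.asarray(ess[v]).ravel() for v in ess.data_vars])
    max_rhat = (float(np.nanmax(rhat_vals))
                if np.isfinite(rhat_vals).any() else float("nan"))
    min_ess = (float(np.nanmin(ess_vals)) / total
               if np.isfinite(ess_vals).any() else float("nan"))
    return ConvergenceReport(
        passed=flagged.empty, flagged=flagged,
        max_rhat=max_rhat, min_ess_ratio=min_ess, notes=notes,
    )


def summarize_posterior(result: PosteriorResult, group: int = 0) -> dict:
    """Posterior medians, 95% central intervals, and block-level reporting.

    Returns a dict of DataFrames: ``parameters`` (per free parameter),
    ``hyperparameters``, and ``blocks`` — per block of ``group`` the
    fakability median and interval plus the percentage of persons whose
    posterior-median faking probability exceeds .5 ("predicted to fake").
    """
    rows = []

    def add(name: str, draws2d: np.ndarray, labels=None):
        med, lo, hi = _central_interval(draws2d)
        for i in range(draws2d.shape[1]):
            label = labels[i] if labels is not None else i
            rows.append({"parameter": name, "index": label,
                         "median": med[i], "q2.5": lo[i], "q97.5": hi[i]})

    kb, r = result.model.n_param_blocks, result.model.n_orders
    beta_flat = result.flat(result.beta)[:, :, 1:].reshape(-1, kb * (r - 1))
    add("beta", beta_flat,
        [f"b{k}:r{u + 2}" for k in range(kb) for u in range(r - 1)])
    add("theta", result.flat(result.theta))
    params = pd.DataFrame(rows)

    hyper_rows = []
    hyper = {
        "M(theta)": result.flat(result.m_theta)[:, None],
        "Var(theta)": result.flat(result.var_theta)[:, None],
        "Var(beta)": result.flat(result.var_beta)[:, None],
    }
    for name, draws in hyper.items():
        med, lo, hi = _central_interval(draws)
        hyper_rows.append({"parameter": name, "median": med[0],
                           "q2.5": lo[0], "q97.5": hi[0]})
    hypers = pd.DataFrame(hyper_rows)

    fp = result.faking_probability_medians(group)
    alpha_g = result.flat(result.group_alpha(group))
    med, lo, hi = _central_interval(alpha_g)
    blocks = pd.DataFrame({
        "block": np.arange(1, fp.shape[1] + 1),
        "alpha_median": med,
        "alpha_q2.5": lo,
        "alpha_q97.5": hi,
        "pct_predicted_to_fake": 100.0 * (fp > 0.5).mean(axis=0),
    })
    return {"parameters": params, "hyperparameters": hypers, "blocks": blocks}
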