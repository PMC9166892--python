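"""Bayesian estimation: density oracle, gradients, fits, diagnostics."""

import numpy as np
import pytest
from scipy import stats

import fakemix as fm
from fakemix.errors import DataError
from fakemix.estimation import PriorConfig, _build_model
from fakemix.mixture import block_fakability, faking_rank_probabilities


def build_model(sim_dataset, priors=None):
    k = sim_dataset["honest"].n_blocks
    return _build_model(
        [sim_dataset["responses"]], [sim_dataset["honest"].probs],
        [np.arange(k)], k, priors or PriorConfig(),
    )


class TestLogDensityOracle:
    def test_matches_likelihood_plus_priors(self, sim_dataset, rng):
        """Sampler log density == public log likelihood + scipy prior densities."""
        model = build_model(sim_dataset)
        k, r = 6, 6
        for _ in range(5):
            bf = rng.normal(size=(k, r - 1))
            th = rng.normal(size=60)
            m, vt, vb = rng.normal(1, 1), rng.uniform(0.1, 2), rng.uniform(0.5, 14)
            got = model.log_density(bf, th, m, vt, vb)
            want = fm.log_likelihood(
                sim_dataset["responses"], fm.RankOrderParameters.from_free(bf),
                th, sim_dataset["honest"].probs,
            )
            want += stats.norm.logpdf(bf, 0, np.sqrt(vb)).sum()
            want += stats.norm.logpdf(th, m, np.sqrt(vt)).sum()
            want += stats.norm.logpdf(m, 1, 2)
            want += stats.invgamma.logpdf(vt, 1.5, scale=1)
            want += stats.truncnorm.logpdf(vb, -0.5, 1.0, loc=5, scale=10)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-8)

    def test_fixed_variances_drop_their_priors(self, sim_dataset, rng):
        model = build_model(sim_dataset, PriorConfig.empirical())
        assert not model.sample_var_theta and not model.sample_var_beta
        bf = rng.normal(size=(6, 5))
        th = rng.normal(size=60)
        got = model.log_density(bf, th, 0.5)
        want = fm.log_likelihood(
            sim_dataset["responses"], fm.RankOrderParameters.from_free(bf),
            th, sim_dataset["honest"].probs,
        )
        want += stats.norm.logpdf(bf, 0, 2.0).sum()          # sd = sqrt(4)
        want += stats.norm.logpdf(th, 0.5, 0.5).sum()        # sd = sqrt(.25)
        want += stats.norm.logpdf(0.5, 1, 2)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-8)


class TestGradients:
    @pytest.mark.parametrize("priors", [
        PriorConfig(), PriorConfig.empirical(), PriorConfig(fix_var_theta=0.25),
    ])
    def test_analytic_gradient_matches_finite_differences(self, sim_dataset,
                                                          priors, rng):
        model = build_model(sim_dataset, priors)
        x = rng.normal(scale=0.3, size=model.dim)
        _, grad = model.logp_grad(x)
        h = 1e-6
        for i in rng.choice(model.dim, size=25, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num = (model.logp_grad(xp)[0] - model.logp_grad(xm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=5e-5, abs=1e-5)


class TestFit:
    def test_posterior_result_structure(self, fitted_result):
        res = fitted_result
        assert res.beta.shape == (2, 250, 6, 6)
        assert np.all(res.beta[:, :, :, 0] == 0)       # reference respected per draw
        assert res.theta.shape == (2, 250, 60)
        assert np.all(res.var_theta > 0) and np.all(res.var_beta > 0)
        assert np.all(res.var_beta < 15)               # truncation respected

    def test_derived_quantities_recomputed_per_draw(self, fitted_result):
        res = fitted_result
        probs = faking_rank_probabilities(res.beta[1, 17])
        np.testing.assert_allclose(res.rank_probs[1, 17], probs, atol=1e-12)
        np.testing.assert_allclose(
            res.alpha[1, 17], block_fakability(probs), atol=1e-12
        )
        # posterior median of alpha summarizes per-draw alphas
        med = np.median(res.flat(res.alpha), axis=0)
        recomputed = np.median(
            block_fakability(faking_rank_probabilities(res.flat(res.beta))), axis=0
        )
        np.testing.assert_allclose(med, recomputed, atol=1e-12)

    def test_no_faking_data_yields_low_faking_probability(self, sim_dataset):
        # responses identical to honest responding: the posterior predicts
        # (almost) nobody to fake
        sampler = fm.SamplerConfig(n_chains=1, n_iterations=500, n_warmup=250)
        res = fm.fit_faking_mixture(
            sim_dataset["honest_responses"], sim_dataset["honest"],
            sampler=sampler, seed=7,
        )
        fp = res.faking_probability_medians()
        assert fp.mean() < 0.25

    def test_bad_inputs_rejected(self, sim_dataset):
        bad = sim_dataset["responses"].copy()
        bad[0, 0] = 9
        with pytest.raises(DataError):
            fm.fit_faking_mixture(bad, sim_dataset["honest"])
        with pytest.raises(DataError):
            fm.fit_faking_mixture(sim_dataset["responses"][:, :3],
                                  sim_dataset["honest"])


class TestSummaries:
    def test_summary_tables_schema(self, fitted_result):
        out = fm.summarize_posterior(fitted_result)
        assert set(out) == {"parameters", "hyperparameters", "blocks"}
        blocks = out["blocks"]
        assert list(blocks.columns) == [
            "block", "alpha_median", "alpha_q2.5", "alpha_q97.5",
            "pct_predicted_to_fake",
        ]
        assert len(blocks) == 6
        assert blocks["pct_predicted_to_fake"].between(0, 100).all()
        assert (blocks["alpha_q2.5"] <= blocks["alpha_median"]).all()
        assert (blocks["alpha_median"] <= blocks["alpha_q97.5"]).all()
        assert set(out["hyperparameters"]["parameter"]) == {
            "M(theta)", "Var(theta)", "Var(beta)",
        }

    def test_no_faking_probabilities_above_half_gives_zero_predicted(
            self, fitted_result):
        res = fitted_result
        fp = res.faking_probability_medians()
        pct = 100.0 * (fp > 0.5).mean(axis=0)
        blocks = fm.summarize_posterior(res)["blocks"]
        np.testing.assert_allclose(blocks["pct_predicted_to_fake"], pct)
        assert np.all(pct[fp.max(axis=0) <= 0.5] == 0)


class TestConvergenceCheck:
    def _result_with_draws(self, fitted_result, shift=0.0):
        """Clone the fitted result with synthetic two-chain draws."""
        import copy

        res = copy.copy(fitted_result)
        rng = np.random.default_rng(0)
        c, d = 2, 1500
        base = rng.standard_normal((c, d, 6, 6))
        base[1] = base[0]                        # duplicated draws
        base[:, :, :, 0] = 0
        base[1] += shift
        res.beta = base
        theta = rng.standard_normal((1, d, 60))
        res.theta = np.concatenate([theta, theta + shift])
        m = rng.standard_normal((1, d))
        res.m_theta = np.concatenate([m, m])
        v = np.exp(rng.standard_normal((1, d)) * 0.1)
        res.var_theta = np.concatenate([v, v])
        res.var_beta = np.concatenate([v, v])
        a = rng.standard_normal((1, d, 6))
        res.alpha = np.concatenate([a, a])
        res.rank_probs = np.full((c, d, 6, 6), 1 / 6)
        return res

    def test_identical_chains_pass(self, fitted_result):
        res = self._result_with_draws(fitted_result, shift=0.0)
        report = fm.convergence_check(res)
        assert report.passed
        assert report.max_rhat < 1.01

    def test_shifted_chains_fail_and_name_parameters(self, fitted_result):
        res = self._result_with_draws(fitted_result, shift=3.0)
        report = fm.convergence_check(res)
        assert not report.passed
        assert (report.flagged["rhat"] >= 1.01).any()
        assert report.flagged["parameter"].str.contains("theta").any()

    def test_threshold_is_strict(self, fitted_result):
        res = self._result_with_draws(fitted_result, shift=0.0)
        report = fm.convergence_check(res, rhat_threshold=1.0)
        # rhat >= threshold flags, so a threshold of exactly 1.0 flags noise
        assert not report.passed


class TestMultigroup:
    def test_all_shared_matches_pooled_dimension(self, sim_dataset):
        h = sim_dataset["honest"]
        resp = sim_dataset["responses"]
        sampler = fm.SamplerConfig(n_chains=1, n_iterations=120, n_warmup=60)
        res = fm.fit_multigroup(resp[:30], resp[30:], h.probs[:30], h.probs[30:],
                                shared_blocks=range(6), sampler=sampler, seed=1)
        assert res.model.n_param_blocks == 6       # fully shared == pooled
        assert res.alpha_difference().shape[2] == 0
        assert res.theta.shape[2] == 60

    def test_partially_shared_layout_and_differences(self, sim_dataset):
        h = sim_dataset["honest"]
        resp = sim_dataset["responses"]
        sampler = fm.SamplerConfig(n_chains=1, n_iterations=120, n_warmup=60)
        res = fm.fit_multigroup(resp[:30], resp[30:], h.probs[:30], h.probs[30:],
                                shared_blocks=[0, 2, 4], sampler=sampler, seed=2)
        assert res.model.n_param_blocks == 3 + 2 * 3
        diff = res.alpha_difference()
        assert diff.shape[2] == 3                  # blocks 1, 3, 5
        # difference draws recompute from the two groups' alphas
        manual = res.group_alpha(1) - res.group_alpha(0)
        np.testing.assert_allclose(diff, manual[:, :, [1, 3, 5]], atol=1e-12)

    def test_inconsistent_block_structure_rejected(self, sim_dataset):
        h = sim_dataset["honest"]
        resp = sim_dataset["responses"]
        with pytest.raises(fm.ConfigurationError):
            fm.fit_multigroup(resp[:30], resp[30:], h.probs[:30],
                              h.probs[30:, :4], shared_blocks=[0])
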