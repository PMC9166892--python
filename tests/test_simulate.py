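"""The data generator: condition grid, traits, item parameters, responses."""

import numpy as np
import pytest

import fakemix as fm
from fakemix.errors import ConfigurationError, InvalidDesignError
from fakemix.simulate import _has_linear_dependency


class TestConditionGrid:
    def test_full_crossing(self):
        grid = fm.condition_grid()
        assert len(grid) == 18
        assert len(set(grid)) == 18
        assert fm.SimulationCondition("low", 0.0, 0.2) in grid
        assert fm.SimulationCondition("high", 2.0, 1.0) in grid

    def test_bad_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            fm.SimulationCondition("medium", 0.0, 0.2)
        with pytest.raises(ConfigurationError):
            fm.SimulationCondition("low", 0.0, -0.1)

    def test_off_design_levels_allowed(self):
        assert not fm.SimulationCondition("low", 0.5, 0.3).on_design


class TestContentTraits:
    def test_default_matrix_values(self):
        corr = fm.big_five_correlations()
        assert corr[0, 1] == -0.36        # neuroticism-extraversion
        assert corr[3, 4] == 0.43         # agreeableness-conscientiousness
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.all(np.linalg.eigvalsh(corr) > 0)

    def test_sample_correlations_match_target(self):
        draws = fm.draw_content_traits(100_000, rng=1)
        sample = np.corrcoef(draws.T)
        np.testing.assert_allclose(sample, fm.big_five_correlations(), atol=0.02)

    def test_identity_gives_independent_columns(self):
        draws = fm.draw_content_traits(50_000, corr=np.eye(3), rng=2)
        off = np.corrcoef(draws.T) - np.eye(3)
        assert np.max(np.abs(off)) < 0.02

    def test_non_pd_matrix_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ConfigurationError):
            fm.draw_content_traits(10, corr=bad, rng=0)


class TestItemParameters:
    def test_parameter_ranges_and_standardization(self):
        design = fm.draw_item_parameters(n_blocks=30, rng=3)
        lam = np.abs(design.loadings)
        assert np.all((lam >= 0.65) & (lam <= 0.95))
        assert np.all((design.intercepts > -1) & (design.intercepts < 1))
        np.testing.assert_array_equal(
            design.error_variances, 1 - design.loadings**2
        )

    def test_default_keying_mixes_signs(self):
        design = fm.draw_item_parameters(n_blocks=25, rng=4)
        negatives = (design.loadings < 0).sum(axis=1)
        # one reversed item per triplet: 2 of 3 pairwise comparisons mixed
        assert np.all(negatives == 1)

    def test_proportional_loadings_detected(self):
        assert _has_linear_dependency(np.array([0.7, 0.7, 0.9]))
        assert _has_linear_dependency(np.array([0.66, 0.726, 0.7986]))  # geometric
        assert not _has_linear_dependency(np.array([0.68, 0.79, 0.93]))

    def test_rejection_cap_raises(self, monkeypatch):
        monkeypatch.setattr(
            "fakemix.simulate._has_linear_dependency", lambda *a, **k: True
        )
        with pytest.raises(InvalidDesignError, match="keying plan"):
            fm.draw_item_parameters(n_blocks=2, rng=5, max_redraws=10)


class TestHonestResponses:
    def test_deterministic_order_with_negligible_noise(self):
        design = fm.BlockDesign.from_arrays(
            intercepts=[[2.0, 1.0, 0.0]], loadings=[[0.0, 0.0, 0.0]],
            error_variances=[[1e-12, 1e-12, 1e-12]], trait_index=[[0, 1, 2]],
        )
        resp = fm.simulate_honest_responses(design, np.zeros((10, 3)), rng=0)
        assert np.all(resp == 1)  # order 1-2-3

    def test_frequencies_match_analytic_probabilities(self, small_design):
        trait = fm.draw_content_traits(1, rng=7)
        honest = fm.honest_probability_table(small_design, trait)
        reps = 30_000
        resp = fm.simulate_honest_responses(
            small_design, np.tile(trait, (reps, 1)), rng=8
        )
        for k in range(small_design.n_blocks):
            freq = np.bincount(resp[:, k] - 1, minlength=6) / reps
            se = np.sqrt(honest.probs[0, k] * (1 - honest.probs[0, k]) / reps)
            assert np.all(np.abs(freq - honest.probs[0, k]) < 3 * se + 1e-3)

    def test_seed_reproducibility(self, small_design, small_traits):
        a = fm.simulate_honest_responses(small_design, small_traits, rng=9)
        b = fm.simulate_honest_responses(small_design, small_traits, rng=9)
        np.testing.assert_array_equal(a, b)


class TestFakingParameters:
    def test_beta_identified_and_theta_moments(self):
        cond = fm.SimulationCondition("high", 2.0, 1.0)
        beta, theta = fm.draw_faking_parameters(cond, n_blocks=2000, n_orders=6,
                                                n_persons=50_000, rng=10)
        assert np.all(beta.beta[:, 0] == 0)
        assert theta.theta.mean() == pytest.approx(2.0, abs=0.05)
        assert theta.theta.var() == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("level, band", [("low", (0.3, 0.6)), ("high", (0.4, 0.9))])
    def test_fakability_bands(self, level, band):
        # the central 90% band of the per-block maximum rank-order
        # probability, reported to one decimal in the design description
        maxima = fm.max_rank_probability_sample(level, n_blocks=50_000, rng=11)
        q05, q95 = np.quantile(maxima, [0.05, 0.95])
        assert q05 == pytest.approx(band[0], abs=0.075)
        assert q95 == pytest.approx(band[1], abs=0.075)


class TestFakingResponses:
    def test_no_faking_limit(self, sim_dataset):
        out = fm.simulate_faking_responses(
            sim_dataset["honest_responses"], sim_dataset["beta"],
            np.full(60, -40.0), rng=12,
        )
        np.testing.assert_array_equal(out, sim_dataset["honest_responses"])

    def test_always_faking_matches_softmax(self, sim_dataset):
        honest = np.tile(sim_dataset["honest_responses"][:1], (20_000, 1))
        out = fm.simulate_faking_responses(
            honest, sim_dataset["beta"], np.full(20_000, 40.0), rng=13,
        )
        probs = sim_dataset["beta"].probabilities()
        for k in range(probs.shape[0]):
            freq = np.bincount(out[:, k] - 1, minlength=6) / 20_000
            se = np.sqrt(probs[k] * (1 - probs[k]) / 20_000)
            assert np.all(np.abs(freq - probs[k]) < 3 * se + 1e-3)

    def test_faked_fraction_matches_probit_expectation(self, sim_dataset):
        honest = sim_dataset["honest_responses"]
        beta, theta = sim_dataset["beta"], sim_dataset["theta"]
        stack = [
            fm.simulate_faking_responses(honest, beta, theta, rng=seed) != honest
            for seed in range(40)
        ]
        changed = np.mean(stack, axis=0).mean(axis=0)          # per block
        expected = fm.faking_probability(
            theta.theta[:, None], beta.fakability()[None, :]
        )
        # a faked block may redraw the honest order: changed = p_fake * (1 - P(same))
        probs = beta.probabilities()
        resp0 = honest - 1
        same = probs[np.arange(probs.shape[0])[None, :], resp0]
        adj = (expected * (1 - same)).mean(axis=0)
        np.testing.assert_allclose(changed, adj, atol=0.03)

    def test_seed_reproducibility(self, sim_dataset):
        a = fm.simulate_faking_responses(sim_dataset["honest_responses"],
                                         sim_dataset["beta"], sim_dataset["theta"],
                                         rng=14)
        b = fm.simulate_faking_responses(sim_dataset["honest_responses"],
                                         sim_dataset["beta"], sim_dataset["theta"],
                                         rng=14)
        np.testing.assert_array_equal(a, b)
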