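"""Shared fixtures: small synthetic questionnaires and a reusable fitted model."""

import numpy as np
import pytest

import fakemix as fm


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_design():
    """4 triplet blocks over 5 traits, standardized item parameters."""
    return fm.draw_item_parameters(n_blocks=4, block_size=3, n_traits=5,
                                   rng=np.random.default_rng(101))


@pytest.fixture(scope="session")
def small_traits():
    return fm.draw_content_traits(40, rng=np.random.default_rng(102))


@pytest.fixture(scope="session")
def small_honest(small_design, small_traits):
    return fm.honest_probability_table(small_design, small_traits)


@pytest.fixture(scope="session")
def sim_dataset():
    """A complete simulated high-stakes dataset (60 persons, 6 blocks)."""
    rng = np.random.default_rng(202)
    design = fm.draw_item_parameters(n_blocks=6, block_size=3, n_traits=5, rng=rng)
    traits = fm.draw_content_traits(60, rng=rng)
    honest = fm.honest_probability_table(design, traits)
    honest_resp = fm.simulate_honest_responses(design, traits, rng=rng)
    condition = fm.SimulationCondition("high", 1.0, 0.5)
    beta, theta = fm.draw_faking_parameters(condition, n_blocks=6, n_orders=6,
                                            n_persons=60, rng=rng)
    responses = fm.simulate_faking_responses(honest_resp, beta, theta, rng=rng)
    return {
        "design": design, "traits": traits, "honest": honest,
        "honest_responses": honest_resp, "condition": condition,
        "beta": beta, "theta": theta, "responses": responses,
    }


@pytest.fixture(scope="session")
def fitted_result(sim_dataset):
    """A short two-chain fit of the simulated dataset (reused across tests)."""
    sampler = fm.SamplerConfig(n_chains=2, n_iterations=500, n_warmup=250)
    return fm.fit_faking_mixture(
        sim_dataset["responses"], sim_dataset["honest"],
        sampler=sampler, seed=303,
    )
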