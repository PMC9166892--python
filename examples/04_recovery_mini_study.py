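"""A miniature parameter-recovery study on a two-condition grid.

Runs simulate -> fit -> score for two design conditions (low vs high
fakability) with two replications each at reduced scale, and prints the
per-condition recovery metrics.  Runtime: ~40 s; the full-scale study is
the same call with 18 conditions, 500 persons, 20 blocks and the
`SamplerConfig.simulation()` preset.
"""

import fakemix as fm

report = fm.run_recovery_study(
    conditions=[
        fm.SimulationCondition("low", 1.0, 0.5),
        fm.SimulationCondition("high", 1.0, 0.5),
    ],
    n_replications=2,
    n_persons=100,
    n_blocks=6,
    sampler=fm.SamplerConfig(n_chains=1, n_iterations=600, n_warmup=300),
    seed=0,
)

print(report.to_text())
print(
    "\nEach row aggregates one parameter family in one condition: 'coverage'\n"
    "is the share of true values inside their 95% posterior intervals,\n"
    "'correlation' relates true values to posterior medians, and the bias\n"
    "columns summarize posterior-median minus truth.  Rank-order parameters\n"
    "(beta) recover best when many respondents fake; the small negative\n"
    "beta bias is a known consequence of the sum-to-one constraint on the\n"
    "faking rank-order probabilities."
)
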