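"""Recovery metrics, the ANOVA decomposition, and the study harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

import fakemix as fm
from fakemix.errors import DataError
from fakemix.recovery import FACTORS, _metrics_for, variance_explained


def anova_ss_oracle(df):
    """Independent sums-of-squares oracle via statsmodels OLS (type-I on a
    balanced design is orthogonal, so the decomposition is unique)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df.copy()
    for f in FACTORS:
        d[f] = d[f].astype(str)
    model = smf.ols(
        "value ~ C(fakability) * C(theta_mean) * C(theta_var)", data=d
    ).fit()
    table = sm.stats.anova_lm(model, typ=1)
    total = table["sum_sq"].sum()
    return {idx: 100.0 * v / total for idx, v in table["sum_sq"].items()}


def metric_table(fn, n_reps=3, seed=0):
    """Build a replication-level metric table over the full grid."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, rep in itertools.product(fm.condition_grid(), range(n_reps)):
        rows.append({
            "fakability": cond.fakability, "theta_mean": cond.theta_mean,
            "theta_var": cond.theta_variance, "replication": rep,
            "value": fn(cond, rep, rng),
        })
    return pd.DataFrame(rows)


class TestRecoveryMetrics:
    def test_hand_computed_fixture(self):
        """Five parameters, two symmetric draws: metrics match a by-hand sheet."""
        true = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        med = np.array([0.1, 0.9, 2.2, 2.8, 4.1])
        half = np.array([1.0, 1.0, 0.05, 1.0, 1.0])
        draws = np.stack([med - half, med + half])           # median == med
        out = _metrics_for(true, draws)
        bias = med - true                                    # [.1,-.1,.2,-.2,.1]
        assert out["mean_bias"] == pytest.approx(bias.mean())
        assert out["sd_bias"] == pytest.approx(np.std(bias, ddof=1))
        assert out["correlation"] == pytest.approx(np.corrcoef(true, med)[0, 1])
        # parameter 3 has a tight interval [2.15, 2.25] missing true = 2
        assert out["coverage"] == pytest.approx(4 / 5)

    def test_perfect_estimates(self):
        true = np.linspace(-1, 1, 7)
        draws = np.tile(true, (10, 1))
        out = _metrics_for(true, draws)
        assert out["mean_bias"] == 0 and out["coverage"] == 1
        assert out["correlation"] == pytest.approx(1.0)

    def test_infinite_intervals_cover(self):
        true = np.array([0.0, 5.0])
        draws = np.array([[-np.inf, -np.inf], [np.inf, np.inf], [0.0, 0.0]])
        assert _metrics_for(true, draws)["coverage"] == 1.0

    def test_compute_recovery_families_and_alignment(self, sim_dataset,
                                                     fitted_result):
        true = fm.TrueParameters(sim_dataset["beta"], sim_dataset["theta"],
                                 sim_dataset["condition"])
        rec = fm.compute_recovery(true, fitted_result)
        assert set(rec.table["family"]) == {
            "theta", "beta", "m_theta", "var_theta", "var_beta",
            "alpha", "rank_probs",
        }
        assert rec.table["coverage"].between(0, 1).all()
        corr = rec.table.set_index("family")["correlation"]
        assert abs(corr["beta"]) <= 1
        # misalignment is reported with the family named
        short = fm.TrueParameters(
            fm.RankOrderParameters.from_free(np.zeros((3, 5))),
            sim_dataset["theta"], sim_dataset["condition"],
        )
        with pytest.raises(DataError, match="beta"):
            fm.compute_recovery(short, fitted_result)


class TestVarianceExplained:
    def test_constant_metric_is_all_residual(self):
        df = metric_table(lambda c, r, g: 0.7)
        out = variance_explained(df)
        assert out["residual"] == pytest.approx(100.0)
        assert out.drop("residual").abs().max() == pytest.approx(0.0)

    def test_pure_factor_effect(self):
        df = metric_table(lambda c, r, g: 1.0 if c.fakability == "high" else 0.0)
        out = variance_explained(df)
        assert out["fakability"] == pytest.approx(100.0)
        assert out["residual"] == pytest.approx(0.0, abs=1e-9)

    def test_random_metric_matches_statsmodels_oracle(self):
        df = metric_table(lambda c, r, g: g.normal(), seed=42)
        ours = variance_explained(df)
        oracle = anova_ss_oracle(df)
        mapping = {
            "fakability": "C(fakability)",
            "theta_mean": "C(theta_mean)",
            "theta_var": "C(theta_var)",
            "fakability:theta_mean": "C(fakability):C(theta_mean)",
            "fakability:theta_var": "C(fakability):C(theta_var)",
            "theta_mean:theta_var": "C(theta_mean):C(theta_var)",
            "fakability:theta_mean:theta_var":
                "C(fakability):C(theta_mean):C(theta_var)",
            "residual": "Residual",
        }
        for ours_key, oracle_key in mapping.items():
            assert ours[ours_key] == pytest.approx(oracle[oracle_key], abs=1e-8)
        assert ours.sum() == pytest.approx(100.0, abs=0.5)

    def test_empty_cells_rejected(self):
        df = metric_table(lambda c, r, g: g.normal())
        partial = df[~((df.fakability == "low") & (df.theta_mean == 0.0)
                       & (df.theta_var == 0.2))]
        with pytest.raises(DataError, match="empty"):
            variance_explained(partial)

    def test_single_replication_rejected(self):
        df = metric_table(lambda c, r, g: g.normal(), n_reps=1)
        with pytest.raises(DataError, match="replication"):
            variance_explained(df)


class TestRunRecoveryStudy:
    @pytest.fixture(scope="class")
    def mini_report(self):
        conditions = [fm.SimulationCondition("low", 1.0, 0.5),
                      fm.SimulationCondition("high", 1.0, 0.5)]
        sampler = fm.SamplerConfig(n_chains=1, n_iterations=300, n_warmup=150)
        return fm.run_recovery_study(
            conditions=conditions, n_replications=2, n_persons=40, n_blocks=4,
            sampler=sampler, seed=5,
        )

    def test_mini_grid_report_well_formed(self, mini_report):
        rep = mini_report
        assert not rep.failures
        assert set(rep.metrics["family"]) >= {"theta", "beta", "alpha"}
        assert len(rep.metrics) == 2 * 2 * 7          # cond x rep x family
        assert rep.config["reduced_scale"] is True
        assert {"fakability", "family", "coverage_mean"} <= set(
            rep.condition_summary.columns
        )
        assert rep.variance is None                   # not a crossed grid
        text = rep.to_text()
        assert "Condition means" in text

    def test_report_regenerates_bit_identically(self, mini_report):
        conditions = [fm.SimulationCondition("low", 1.0, 0.5),
                      fm.SimulationCondition("high", 1.0, 0.5)]
        sampler = fm.SamplerConfig(n_chains=1, n_iterations=300, n_warmup=150)
        again = fm.run_recovery_study(
            conditions=conditions, n_replications=2, n_persons=40, n_blocks=4,
            sampler=sampler, seed=5,
        )
        pd.testing.assert_frame_equal(mini_report.metrics, again.metrics)

    def test_pooled_sd_bias_option(self):
        sampler = fm.SamplerConfig(n_chains=1, n_iterations=200, n_warmup=100)
        kwargs = dict(
            conditions=[fm.SimulationCondition("high", 1.0, 0.5)],
            n_replications=2, n_persons=30, n_blocks=3,
            sampler=sampler, seed=9,
        )
        per_rep = fm.run_recovery_study(**kwargs)
        pooled = fm.run_recovery_study(**kwargs, sd_bias_pooling="pooled")
        assert pooled.config["sd_bias_pooling"] == "pooled"
        # replication-level metrics are identical; only aggregation differs
        pd.testing.assert_frame_equal(per_rep.metrics, pooled.metrics)
        a = per_rep.condition_summary.set_index("family")["sd_bias_mean"]
        b = pooled.condition_summary.set_index("family")["sd_bias_mean"]
        assert np.isfinite(b["beta"])
        assert b["beta"] != a["beta"]      # pooling includes between-rep spread

    def test_json_roundtrip(self, mini_report, tmp_path):
        import json

        path = tmp_path / "report.json"
        mini_report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["config"]["n_replications"] == 2
        assert len(payload["metrics"]) == len(mini_report.metrics)
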