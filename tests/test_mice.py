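import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from prevcast.imputers import draw_binary_imputation, fit_binary_logistic, main
from prevcast.mice import (
    EngineConfig,
    EngineError,
    default_models,
    initialize,
    run,
    trace_summary,
)
from prevcast.pooling import cell_prevalence, rubin_pool
from prevcast.survey import SurveyTable, VariableSpec

from conftest import make_random_table


def bernoulli_table(n, p_miss, rng, p=0.5):
    """MCAR fixture: one Bernoulli(p) indicator, missing completely at random."""
    df = pd.DataFrame(
        {
            "year": 2000.0,
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.integers(25, 65, size=n).astype(float),
            "smoking": (rng.random(n) < p).astype(float),
        }
    )
    df.loc[rng.random(n) < p_miss, "smoking"] = np.nan
    schema = [
        VariableSpec("year", "design", "continuous"),
        VariableSpec("sex", "design", "categorical", levels=("male", "female")),
        VariableSpec("age", "design", "continuous"),
        VariableSpec("smoking", "outcome", "binary", imputable=True),
    ]
    return SurveyTable(df, schema)


class TestEngineConfig:
    def test_defaults_match_standard_settings(self):
        config = EngineConfig(models={})
        assert config.m == 50
        assert config.iterations == 10

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            EngineConfig(models={}, m=1)


class TestInitialize:
    def test_complete_table_unchanged(self, minimal_schema):
        rng = np.random.default_rng(0)
        table = make_random_table(rng, 50, minimal_schema, missing_rate=0.0)
        df, mask = initialize(table, rng)
        pd.testing.assert_frame_equal(df, table.df)
        assert not mask.any().any()

    def test_fills_from_observed_support(self, minimal_schema):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "year": [2000.0] * 6,
                "sex": ["male"] * 6,
                "age": [40.0] * 6,
                "smoking": [1.0, 1.0, 1.0, np.nan, np.nan, np.nan],
            }
        )
        table = SurveyTable(df, minimal_schema)
        filled, _ = initialize(table, rng)
        assert (filled["smoking"] == 1.0).all()

    def test_fully_missing_variable_rejected(self, minimal_schema):
        df = pd.DataFrame(
            {"year": [2000.0], "sex": ["male"], "age": [40.0],
             "smoking": [np.nan]}
        )
        with pytest.raises(EngineError):
            initialize(SurveyTable(df, minimal_schema), np.random.default_rng(0))


class TestRun:
    def test_no_missing_gives_identical_copies(self, minimal_schema):
        rng = np.random.default_rng(2)
        table = make_random_table(rng, 60, minimal_schema, missing_rate=0.0)
        config = EngineConfig(models=default_models(table), m=3, iterations=2,
                              seed=1)
        stack = run(table, config)
        assert stack.m == 3
        assert stack.traces.empty
        for ds in stack.datasets:
            pd.testing.assert_frame_equal(ds.df, table.df)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(3)
        table = bernoulli_table(500, 0.4, rng)
        config = EngineConfig(models=default_models(table), m=3, iterations=3,
                              seed=7)
        stack = run(table, config)
        observed = table.df["smoking"].notna()
        for ds in stack.datasets:
            pd.testing.assert_series_equal(
                ds.df.loc[observed, "smoking"],
                table.df.loc[observed, "smoking"],
            )
            assert not ds.df["smoking"].isna().any()

    def test_same_seed_reproduces_stack(self):
        rng = np.random.default_rng(4)
        table = bernoulli_table(300, 0.3, rng)
        config = EngineConfig(models=default_models(table), m=3, iterations=2,
                              seed=11)
        a = run(table, config)
        b = run(table, config)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da.df, db.df)
        pd.testing.assert_frame_equal(a.traces, b.traces)

    def test_missing_model_rejected(self):
        rng = np.random.default_rng(5)
        table = bernoulli_table(50, 0.3, rng)
        with pytest.raises(EngineError, match="smoking"):
            run(table, EngineConfig(models={}, m=2, iterations=1, seed=0))

    def test_mcar_pooled_prevalence_unbiased(self):
        rng = np.random.default_rng(6)
        table = bernoulli_table(2000, 0.5, rng)
        config = EngineConfig(models=default_models(table), m=5, iterations=3,
                              seed=13)
        stack = run(table, config)
        ests = [
            cell_prevalence(ds, "smoking", {"year": 2000.0})
            for ds in stack.datasets
        ]
        pooled = rubin_pool(ests)
        assert abs(pooled.q_bar - 0.5) < 3 * pooled.se

    def test_single_variable_matches_direct_draw(self):
        """With one imputable variable and one iteration, the chained engine
        reduces to a direct posterior-draw imputation from the observed-data
        fit; the two routes must agree distributionally."""
        rng = np.random.default_rng(8)
        table = bernoulli_table(400, 0.5, rng, p=0.4)
        missing = table.df["smoking"].isna().to_numpy()
        observed = ~missing

        # direct route: fit once on observed rows, draw repeatedly
        X = np.column_stack(
            [np.ones(len(table.df)),
             (table.df["sex"] == "female").to_numpy(float),
             table.df["age"].to_numpy(float)]
        )
        fit = fit_binary_logistic(
            X[observed], table.df.loc[observed, "smoking"].to_numpy(float)
        )
        direct_rng = np.random.default_rng(100)
        direct = [
            draw_binary_imputation(fit, X[missing], direct_rng).sum()
            for _ in range(100)
        ]

        config = EngineConfig(
            models=default_models(table), m=2, iterations=1, seed=0
        )
        engine = []
        for seed in range(50):
            stack = run(table, config.with_overrides(seed=200 + seed))
            for ds in stack.datasets:
                engine.append(ds.df.loc[missing, "smoking"].sum())

        n_mis = int(missing.sum())
        total = n_mis * 100
        p1 = sum(direct) / total
        p2 = sum(engine) / total
        p = (sum(direct) + sum(engine)) / (2 * total)
        z = (p1 - p2) / np.sqrt(p * (1 - p) * 2 / total)
        assert abs(z) < stats.norm.ppf(0.995)

    def test_pseudo_wave_fitting_uses_observed_only(self):
        # fully missing pseudo-wave: 100% of its cells need imputation, yet
        # the fit must come from genuinely observed outcomes
        from prevcast.pseudo import (
            PopulationForecast, PseudoSampleSpec, append_future,
            build_pseudo_sample,
        )

        rng = np.random.default_rng(9)
        table = bernoulli_table(400, 0.2, rng)
        fc = PopulationForecast(pd.DataFrame(
            [(2025, s, a, 10.0) for s in ("male", "female")
             for a in range(25, 65)],
            columns=["year", "sex", "age", "count"],
        ))
        pseudo = build_pseudo_sample(
            PseudoSampleSpec(2025, 200), fc, table.schema
        )
        combined = append_future(table, [pseudo])
        config = EngineConfig(models=default_models(combined), m=2,
                              iterations=2, seed=3)
        stack = run(combined, config)
        for ds in stack.datasets:
            pseudo_rows = ds.df["_source"] == "pseudo"
            assert pseudo_rows.sum() == 200
            assert not ds.df.loc[pseudo_rows, "smoking"].isna().any()


class TestTraces:
    def test_trace_shape_m_times_iterations(self):
        rng = np.random.default_rng(10)
        table = bernoulli_table(200, 0.3, rng)
        config = EngineConfig(models=default_models(table), m=2, iterations=3,
                              seed=21)
        out = trace_summary(run(table, config))
        assert len(out) == 2 * 3
        assert set(out.columns) == {
            "variable", "dataset", "iteration", "mean", "variance"
        }

    def test_single_missing_cell_has_zero_variance(self, minimal_schema):
        df = pd.DataFrame(
            {
                "year": [2000.0] * 30,
                "sex": ["male", "female"] * 15,
                "age": np.linspace(25, 64, 30),
                "smoking": [np.nan] + [float(i % 2) for i in range(29)],
            }
        )
        table = SurveyTable(df, minimal_schema)
        config = EngineConfig(models=default_models(table), m=2, iterations=2,
                              seed=0)
        out = trace_summary(run(table, config))
        assert (out["variance"] == 0.0).all()

    def test_stationary_chain_no_drift(self):
        """For a correctly specified model the chain is stationary from the
        start: first-half and second-half trace means should not differ
        (Geweke-style comparison across datasets at the 1% level)."""
        rng = np.random.default_rng(12)
        table = bernoulli_table(1000, 0.4, rng)
        config = EngineConfig(models=default_models(table), m=8, iterations=10,
                              seed=31)
        out = trace_summary(run(table, config))
        first = out[out["iteration"] <= 5].groupby("dataset")["mean"].mean()
        second = out[out["iteration"] > 5].groupby("dataset")["mean"].mean()
        t, p = stats.ttest_rel(first, second)
        assert p > 0.01
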