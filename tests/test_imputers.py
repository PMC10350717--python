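import math

import numpy as np
import pandas as pd
import pytest

from prevcast.imputers import (
    ConvergenceError,
    DegenerateOutcomeError,
    ImputationModel,
    bic,
    build_design,
    draw_binary_imputation,
    draw_polytomous_imputation,
    fit_binary_logistic,
    interaction,
    main,
    select_model,
    spline,
)
from prevcast.survey import SurveyTable, VariableSpec
from prevcast.synthetic import LogitSpec, linear_trend_config, generate_population
from scipy.special import expit


def design(*cols):
    n = len(cols[0])
    return np.column_stack([np.ones(n)] + [np.asarray(c, float) for c in cols])


class TestFitBinaryLogistic:
    def test_balanced_null(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_binary_logistic(np.ones((4, 1)), y, ridge=0.0)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(4 * math.log(0.5), abs=1e-10)

    def test_separation_stays_finite_with_ridge(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        fit = fit_binary_logistic(design(x), y, ridge=1e-5)
        assert np.all(np.isfinite(fit.beta))
        assert np.all(np.isfinite(fit.cov))

    def test_matches_reference_mle_as_ridge_vanishes(self):
        # independent oracle: statsmodels unpenalized logistic MLE
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        z = rng.normal(size=500)
        eta = -0.4 + 0.8 * x - 0.5 * z
        y = (rng.random(500) < expit(eta)).astype(float)
        X = design(x, z)
        ours = fit_binary_logistic(X, y, ridge=1e-10)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-5)
        np.testing.assert_allclose(ours.loglik, ref.llf, atol=1e-7)
        np.testing.assert_allclose(
            ours.cov, ref.cov_params(), rtol=1e-3, atol=1e-6
        )

    def test_one_level_outcome_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_binary_logistic(np.ones((5, 1)), np.ones(5))


class TestDrawBinary:
    def _fit(self, beta, cov):
        from prevcast.imputers import FittedModel

        beta = np.asarray(beta, float)
        return FittedModel(
            beta=beta, cov=np.asarray(cov, float), loglik=0.0,
            n_fit=10, k_par=len(beta),
        )

    def test_certain_probability_gives_all_ones(self):
        fit = self._fit([50.0], np.zeros((1, 1)))
        rng = np.random.default_rng(0)
        draws = draw_binary_imputation(fit, np.ones((20, 1)), rng)
        assert np.all(draws == 1.0)

    def test_half_probability_monte_carlo(self):
        fit = self._fit([0.0], np.zeros((1, 1)))
        rng = np.random.default_rng(1)
        draws = draw_binary_imputation(fit, np.ones((10_000, 1)), rng)
        assert abs(draws.mean() - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_same_seed_identical(self):
        fit = self._fit([0.2, -0.3], 0.01 * np.eye(2))
        X = np.column_stack([np.ones(50), np.linspace(-1, 1, 50)])
        a = draw_binary_imputation(fit, X, np.random.default_rng(9))
        b = draw_binary_imputation(fit, X, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_non_psd_covariance_rejected(self):
        fit = self._fit([0.0], np.array([[-1.0]]))
        with pytest.raises(ValueError, match="semi-definite"):
            draw_binary_imputation(fit, np.ones((3, 1)), np.random.default_rng(0))


class TestDrawPolytomous:
    def test_single_level_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            draw_polytomous_imputation(
                np.ones((5, 1)), np.array(["a"] * 5), np.ones((2, 1)),
                np.random.default_rng(0),
            )

    def test_marginal_recovery_monte_carlo(self):
        rng = np.random.default_rng(11)
        levels = np.array(["a", "b", "c"])
        probs = np.array([0.2, 0.3, 0.5])
        y = rng.choice(levels, size=3000, p=probs)
        X = np.ones((3000, 1))
        draws = draw_polytomous_imputation(
            X, y, np.ones((10_000, 1)), np.random.default_rng(5)
        )
        for lv, p in zip(levels, probs):
            share = (draws == lv).mean()
            # bootstrap + multinomial noise; 3 s.e. with both layers
            se = math.sqrt(p * (1 - p) / 10_000 + p * (1 - p) / 3000)
            assert abs(share - p) < 3 * se

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        y = rng.choice(["a", "b", "c"], size=200)
        X = np.ones((200, 1))
        a = draw_polytomous_imputation(X, y, np.ones((40, 1)),
                                       np.random.default_rng(4))
        b = draw_polytomous_imputation(X, y, np.ones((40, 1)),
                                       np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)


class TestBic:
    def test_closed_form_null(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_binary_logistic(np.ones((4, 1)), y, ridge=0.0)
        assert bic(fit) == pytest.approx(10 * math.log(2), abs=1e-8)

    def test_identical_fits_identical_bic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.4).astype(float)
        a = bic(fit_binary_logistic(design(x), y))
        b = bic(fit_binary_logistic(design(x), y))
        assert a == b

    def test_invariant_to_column_order_and_rescaling(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=400)
        z = rng.normal(size=400)
        y = (rng.random(400) < expit(0.5 * x - 0.3 * z)).astype(float)
        base = bic(fit_binary_logistic(design(x, z), y))
        swapped = bic(fit_binary_logistic(design(z, x), y))
        rescaled = bic(fit_binary_logistic(design(100 * x + 7, z), y))
        assert swapped == pytest.approx(base, abs=1e-6)
        assert rescaled == pytest.approx(base, abs=1e-6)

    def test_noise_predictor_usually_increases_bic(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=3000)
            noise = rng.normal(size=3000)
            y = (rng.random(3000) < expit(0.4 * x)).astype(float)
            b0 = bic(fit_binary_logistic(design(x), y))
            b1 = bic(fit_binary_logistic(design(x, noise), y))
            hits += b1 > b0
        assert hits >= 24  # chi2(1) < ln(3000) happens ~99.5% of the time

    def test_empty_fit_rejected(self):
        from prevcast.imputers import FittedModel

        fit = FittedModel(np.zeros(1), np.eye(1), 0.0, 0, 1)
        with pytest.raises(ValueError):
            bic(fit)


class TestImputationModel:
    def test_outcome_among_predictors_rejected(self):
        with pytest.raises(ValueError):
            ImputationModel("y", (main("y"),), "binary-logistic")

    def test_interaction_requires_two_variables(self):
        with pytest.raises(ValueError):
            interaction("x")


class TestBuildDesign:
    def test_dummy_coding_and_completeness(self):
        schema = [
            VariableSpec("year", "design", "continuous"),
            VariableSpec("sex", "design", "categorical",
                         levels=("male", "female")),
            VariableSpec("age", "design", "continuous"),
            VariableSpec("edu", "covariate", "categorical",
                         levels=("a", "b", "c"), imputable=True),
            VariableSpec("y", "outcome", "binary", imputable=True),
        ]
        df = pd.DataFrame(
            {
                "year": [1997.0, 2002.0, 2007.0],
                "sex": ["male", "female", "male"],
                "age": [30.0, 40.0, 50.0],
                "edu": ["a", np.nan, "c"],
                "y": [0.0, 1.0, 1.0],
            }
        )
        table = SurveyTable(df, schema)
        X, names, complete = build_design(
            table.df, [main("sex"), main("edu"), interaction("sex", "age")],
            table.schema_map,
        )
        assert names == [
            "(Intercept)", "sex[female]", "edu[b]", "edu[c]",
            "sex[female]:age",
        ]
        assert complete.tolist() == [True, False, True]
        np.testing.assert_array_equal(X[0], [1.0, 0.0, 0.0, 0.0, 0.0])
        np.testing.assert_array_equal(X[2], [1.0, 0.0, 0.0, 1.0, 0.0])


class TestSelectModel:
    def test_empty_candidates_returns_base(self):
        cfg = linear_trend_config(300)
        table, _ = generate_population(cfg, np.random.default_rng(0))
        model = select_model(
            table, "risk", [main("sex"), main("age"), main("year")], []
        )
        assert model.terms == (main("sex"), main("age"), main("year"))
        assert model.family == "binary-logistic"

    def test_recovers_strong_interaction(self):
        cfg = linear_trend_config(1500)
        spec = LogitSpec(intercept=-0.8, male=0.3, age=0.3, year=0.3,
                         age_x_year=0.8)
        cfg = type(cfg)(
            waves=cfg.waves, indicators=(("risk", spec),),
            include_covariates=False,
        )
        table, _ = generate_population(cfg, np.random.default_rng(10))
        model = select_model(
            table, "risk", [main("sex"), main("age"), main("year")],
            [interaction("year", "age"), interaction("sex", "age")],
        )
        assert interaction("year", "age") in model.terms

    def test_spline_replaces_linear_year(self):
        cfg = linear_trend_config(1500)
        spec = LogitSpec(intercept=-0.8, male=0.3, age=0.3, year=0.3,
                         year_sq=-1.2)
        cfg = type(cfg)(
            waves=cfg.waves, indicators=(("risk", spec),),
            include_covariates=False,
        )
        table, _ = generate_population(cfg, np.random.default_rng(11))
        model = select_model(
            table, "risk", [main("sex"), main("age"), main("year")],
            [spline("year", 2)],
        )
        assert spline("year", 2) in model.terms
        assert main("year") not in model.terms
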