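"""Chained-equations (fully conditional specification) imputation engine.

The engine takes the combined table — observed survey waves plus fully
missing pseudo-waves — and produces ``m`` completed copies.  For each copy
it starts from random fills drawn from each variable's observed values,
then cycles ``iterations`` times over the incomplete variables.  On each
visit the variable's conditional model is refit on the records where that
variable was *originally observed* (using the current completed values of
all predictors) and every originally missing cell is redrawn.  Originally
observed cells are never altered.

Reproducibility: the master seed spawns one independent random substream
per completed dataset, so datasets are statistically independent chains and
re-running with the same seed reproduces the stack exactly.

Per-iteration means and variances of the imputed values are recorded as
chain traces, the raw material for convergence plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imputers import (
    ImputationModel,
    build_design,
    draw_binary_imputation,
    draw_polytomous_imputation,
    fit_binary_logistic,
    freeze_spline_bases,
    main,
    spline,
)
from .splines import RCSBasis
from .survey import SurveyTable

logger = logging.getLogger(__name__)


class EngineError(RuntimeError):
    """A model fit failed inside the chained-equations loop."""


@dataclass
class EngineConfig:
    """Settings for one imputation run.

    Defaults follow common practice for this projection workflow: 50
    completed datasets, 10 cycles of the chained equations, variables
    visited in ascending order of missing-value count.
    """

    models: dict[str, ImputationModel]
    m: int = 50
    iterations: int = 10
    seed: int = 0
    visit_order: list[str] | None = None  # None = ascending missing count

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need m >= 2 imputed datasets")
        if self.iterations < 1:
            raise ValueError("need >= 1 iteration")

    def with_overrides(self, **kw) -> "EngineConfig":
        return replace(self, **kw)


@dataclass
class ImputedStack:
    """``m`` completed survey tables plus chain traces and the config used."""

    datasets: list[SurveyTable]
    traces: pd.DataFrame  # variable, dataset, iteration, mean, variance
    config: EngineConfig

    @property
    def m(self) -> int:
        return len(self.datasets)


def default_models(
    table: SurveyTable,
    ridge: float = 1e-5,
    year_spline_df: dict[str, int] | None = None,
    extra_terms: dict[str, list] | None = None,
) -> dict[str, ImputationModel]:
    """Main-effects conditional models for every imputable variable.

    Each variable is modelled on the main effects of all other schema
    variables; ``year_spline_df`` swaps the linear year effect for a
    restricted cubic spline for the named outcomes, and ``extra_terms``
    appends e.g. interaction terms.
    """
    year_spline_df = year_spline_df or {}
    extra_terms = extra_terms or {}
    models = {}
    for spec in table.schema:
        if not spec.imputable:
            continue
        terms = []
        for other in table.schema:
            if other.name == spec.name:
                continue
            if other.name == "year" and spec.name in year_spline_df:
                terms.append(spline("year", year_spline_df[spec.name]))
            else:
                terms.append(main(other.name))
        terms.extend(extra_terms.get(spec.name, []))
        family = (
            "binary-logistic" if spec.vtype == "binary" else "polytomous-logistic"
        )
        models[spec.name] = ImputationModel(spec.name, tuple(terms), family, ridge)
    return models


def initialize(
    table: SurveyTable, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill every missing cell with a uniform draw from observed values.

    Returns the completed frame and the original missingness mask.
    """
    df = table.df.copy()
    mask = table.missing_mask()
    for spec in table.schema:
        col_mask = mask[spec.name]
        n_mis = int(col_mask.sum())
        if n_mis == 0:
            continue
        observed = df.loc[~col_mask, spec.name].to_numpy()
        if observed.size == 0:
            raise EngineError(
                f"variable {spec.name!r} has no observed values to start from"
            )
        df.loc[col_mask, spec.name] = rng.choice(observed, size=n_mis)
    return df, mask


def _visit_order(table: SurveyTable, config: EngineConfig) -> list[str]:
    mask = table.missing_mask()
    candidates = [
        s.name
        for s in table.schema
        if s.imputable and mask[s.name].any()
    ]
    if config.visit_order is not None:
        ordered = [v for v in config.visit_order if v in candidates]
        missing = set(candidates) - set(ordered)
        if missing:
            raise ValueError(f"visit_order omits incomplete variables {missing}")
        return ordered
    # ascending missing count, ties broken by schema order (stable sort)
    return sorted(candidates, key=lambda v: int(mask[v].sum()))


def _numeric_codes(values: np.ndarray, spec) -> np.ndarray:
    if spec.vtype == "categorical":
        return pd.Categorical(values, categories=spec.levels).codes.astype(float)
    return np.asarray(values, dtype=float)


def run(table: SurveyTable, config: EngineConfig) -> ImputedStack:
    """Produce ``m`` completed datasets by chained-equations imputation."""
    schema_map = table.schema_map
    mask = table.missing_mask()
    visit = _visit_order(table, config)
    for v in visit:
        if v not in config.models:
            raise EngineError(f"no imputation model for incomplete variable {v!r}")
        model = config.models[v]
        unknown = model.predictor_variables() - set(schema_map)
        if unknown:
            raise EngineError(f"model for {v!r} references unknown {unknown}")
    spline_bases = freeze_spline_bases(table, config.models)

    streams = np.random.SeedSequence(config.seed).spawn(config.m)
    datasets: list[SurveyTable] = []
    trace_rows: list[dict] = []
    for d, ss in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        df, _ = initialize(table, rng)
        for it in range(1, config.iterations + 1):
            for v in visit:
                try:
                    _impute_one(
                        df, v, config.models[v], mask[v].to_numpy(),
                        schema_map, spline_bases, rng,
                    )
                except Exception as exc:
                    raise EngineError(
                        f"imputation of {v!r} failed in dataset {d}, "
                        f"iteration {it}: {exc}"
                    ) from exc
                imp = _numeric_codes(
                    df.loc[mask[v].to_numpy(), v].to_numpy(), schema_map[v]
                )
                trace_rows.append(
                    {
                        "variable": v,
                        "dataset": d,
                        "iteration": it,
                        "mean": float(imp.mean()),
                        "variance": float(imp.var(ddof=0)),
                    }
                )
        completed = SurveyTable(df.copy(), list(table.schema), table.age_range)
        datasets.append(completed)

    traces = pd.DataFrame(
        trace_rows, columns=["variable", "dataset", "iteration", "mean", "variance"]
    )
    return ImputedStack(datasets, traces, config)


def _impute_one(
    df: pd.DataFrame,
    variable: str,
    model: ImputationModel,
    orig_missing: np.ndarray,
    schema_map,
    spline_bases: dict[str, RCSBasis],
    rng: np.random.Generator,
) -> None:
    X, names, complete = build_design(df, model.terms, schema_map, spline_bases)
    if not complete.all():  # predictors are completed data; must be complete
        raise EngineError("incomplete predictors inside the chained loop")
    fit_rows = ~orig_missing
    if model.family == "binary-logistic":
        y = pd.to_numeric(df.loc[fit_rows, variable]).to_numpy(dtype=float)
        fit = fit_binary_logistic(
            X[fit_rows], y, ridge=model.ridge, names=names
        )
        draws = draw_binary_imputation(fit, X[orig_missing], rng)
        df.loc[orig_missing, variable] = draws
    else:
        y = df.loc[fit_rows, variable].to_numpy()
        draws = draw_polytomous_imputation(
            X[fit_rows], y, X[orig_missing], rng, ridge=model.ridge
        )
        df.loc[orig_missing, variable] = draws


def trace_summary(stack: ImputedStack) -> pd.DataFrame:
    """Long-format chain traces (variable, dataset, iteration, mean, variance)."""
    if stack.traces.empty:
        logger.info("no chain traces: the input had no missing values")
        return stack.traces.copy()
    return (
        stack.traces.sort_values(["variable", "dataset", "iteration"])
        .reset_index(drop=True)
    )


__all__ = [
    "EngineConfig",
    "ImputedStack",
    "EngineError",
    "default_models",
    "initialize",
    "run",
    "trace_summary",
]
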