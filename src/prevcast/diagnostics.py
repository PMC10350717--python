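"""Diagnostics for projection runs.

Three checks guard against the characteristic failure modes of projecting
by imputation:

* **correlation structure** — Spearman correlations between indicators and
  covariates, per wave, averaged over the imputed datasets.  In a healthy
  run the fully simulated future waves show the same correlation pattern
  as the observed waves (e.g. hypertension stays strongly age-graded,
  unrelated pairs stay near zero).
* **hold-out validation** — drop the most recent observed wave, project it
  from the earlier waves using a pseudo-sample with the dropped wave's own
  size and age/sex margins, and check whether the projected interval
  covers the observed prevalence.  An abrupt level change in the held-out
  wave *should* make this fail: trend extrapolation cannot anticipate
  shocks.
* **sensitivity comparison** — rerun the pipeline with competing survey-
  year specifications (linear vs restricted cubic spline) under a shared
  seed; materially different projections flag model dependence.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .imputers import ImputationModel, TermSpec
from .mice import EngineConfig, ImputedStack, run
from .pooling import project_prevalences
from .pseudo import (
    PopulationForecast,
    PseudoSampleSpec,
    append_future,
    build_pseudo_sample,
)
from .survey import OBSERVED, PROVENANCE, SurveyTable

logger = logging.getLogger(__name__)


def correlation_structure(
    stack: ImputedStack, variables: list[str]
) -> pd.DataFrame:
    """Spearman correlation per wave and variable pair, averaged over the
    ``m`` imputed datasets.

    Variables must be numeric-codable (binary 0/1 or continuous); a
    variable constant within a wave yields a missing coefficient with a
    logged warning.  Ties are handled by midranks (the standard Spearman
    convention).
    """
    schema_map = stack.datasets[0].schema_map
    for v in variables:
        spec = schema_map.get(v)
        if spec is None:
            raise ValueError(f"unknown variable {v!r}")
        if spec.vtype == "categorical" and v != "sex":
            raise ValueError(
                f"{v!r} is categorical; select a dummy or exclude it"
            )
    pairs = [
        (a, b) for i, a in enumerate(variables) for b in variables[i + 1:]
    ]
    acc: dict[tuple[int, str, str], list[float]] = {}
    for ds in stack.datasets:
        df = ds.df
        for year, wave in df.groupby("year"):
            for a, b in pairs:
                x = _as_numeric(wave, a, schema_map)
                y = _as_numeric(wave, b, schema_map)
                if np.unique(x).size < 2 or np.unique(y).size < 2:
                    rho = np.nan
                else:
                    rho = stats.spearmanr(x, y).statistic
                acc.setdefault((int(year), a, b), []).append(float(rho))
    rows = []
    for (year, a, b), values in sorted(acc.items()):
        arr = np.asarray(values)
        if np.isnan(arr).any():
            logger.warning(
                "constant variable in wave %s for pair (%s, %s)", year, a, b
            )
        rows.append(
            {
                "year": year,
                "var1": a,
                "var2": b,
                "rho": float(np.nanmean(arr)) if not np.isnan(arr).all() else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["year", "var1", "var2", "rho"])


def _as_numeric(df: pd.DataFrame, var: str, schema_map) -> np.ndarray:
    spec = schema_map[var]
    if spec.vtype == "categorical":  # two-level only (sex)
        return (df[var] == spec.levels[1]).to_numpy(dtype=float)
    return pd.to_numeric(df[var]).to_numpy(dtype=float)


def holdout_validation(
    table: SurveyTable,
    holdout_year: int,
    config: EngineConfig,
    indicators: list[str] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Project a withheld wave and compare with what was actually observed.

    The held-out wave is removed from the data; a pseudo-wave with *that
    wave's own* size and (sex, age) margins is appended; the engine and
    Rubin pooling then produce projected prevalences per indicator and sex.
    Observed prevalences use complete cases with a Wald interval.  The
    ``included`` flag records whether the observed point falls inside the
    projected interval.
    """
    df = table.df
    obs = df[(df["year"] == holdout_year) & (df[PROVENANCE] == OBSERVED)]
    if obs.empty:
        raise ValueError(f"hold-out year {holdout_year} absent from the data")
    train = df[(df["year"] != holdout_year) & (df[PROVENANCE] == OBSERVED)]
    if len(pd.unique(train["year"])) < 2:
        raise ValueError("need >= 2 remaining waves to project from")
    train_table = SurveyTable(
        train.reset_index(drop=True), list(table.schema), table.age_range
    )

    # pseudo-wave margins from the observed held-out wave itself
    margins = (
        obs.groupby(["sex", "age"], observed=True).size().reset_index(name="count")
    )
    margins["year"] = holdout_year
    forecast = PopulationForecast(margins[["year", "sex", "age", "count"]])
    age_range = (int(obs["age"].min()), int(obs["age"].max()))
    spec = PseudoSampleSpec(holdout_year, len(obs), age_range)
    pseudo = build_pseudo_sample(spec, forecast, table.schema)
    combined = append_future(train_table, [pseudo])
    stack = run(combined, config)

    if indicators is None:
        indicators = [
            s.name for s in table.schema
            if s.role == "outcome" and s.vtype == "binary"
        ]
    z = float(stats.norm.ppf(0.5 * (1 + level)))
    rows = []
    for ind in indicators:
        proj = project_prevalences(
            stack, ind,
            [{"year": float(holdout_year), "sex": sex}
             for sex in table.schema_map["sex"].levels],
            level=level,
        )
        for sex in table.schema_map["sex"].levels:
            cc = pd.to_numeric(obs.loc[obs["sex"] == sex, ind]).dropna()
            q = float(cc.mean())
            half = z * np.sqrt(q * (1 - q) / len(cc))
            prow = proj[proj["sex"] == sex].iloc[0]
            included = bool(prow["ci_low"] <= q <= prow["ci_high"])
            rows.append(
                {
                    "indicator": ind,
                    "sex": sex,
                    "observed": q,
                    "observed_low": max(0.0, q - half),
                    "observed_high": min(1.0, q + half),
                    "n_complete": len(cc),
                    "projected": float(prow["estimate"]),
                    "projected_low": float(prow["ci_low"]),
                    "projected_high": float(prow["ci_high"]),
                    "included": included,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_compare(
    table: SurveyTable,
    outcome: str,
    config: EngineConfig,
    variants: dict[str, TermSpec],
    forecast: PopulationForecast,
    target_years: list[int],
    size: int,
    level: float = 0.95,
) -> pd.DataFrame:
    """Side-by-side projections under competing survey-year specifications.

    Each variant replaces the year term in the outcome's imputation model
    (e.g. linear vs restricted cubic spline); the whole pipeline reruns per
    variant with the same master seed so differences are attributable to
    the specification.
    """
    if len(variants) < 2:
        raise ValueError("need >= 2 variants to compare")
    lo, hi = table.age_range or (
        int(table.df["age"].min()), int(table.df["age"].max())
    )
    pseudos = [
        build_pseudo_sample(
            PseudoSampleSpec(y, size, (lo, hi)), forecast, table.schema
        )
        for y in target_years
    ]
    combined = append_future(table, pseudos)
    sexes = table.schema_map["sex"].levels
    groups = [
        {"year": float(y), "sex": s} for y in target_years for s in sexes
    ]
    frames = []
    for name, year_term in variants.items():
        models = dict(config.models)
        base = models[outcome]
        terms = tuple(
            t for t in base.terms if t.variables != ("year",)
        ) + (year_term,)
        models[outcome] = ImputationModel(
            base.outcome, terms, base.family, base.ridge
        )
        stack = run(combined, replace(config, models=models))
        proj = project_prevalences(stack, outcome, groups, level=level)
        proj.insert(0, "variant", name)
        frames.append(proj)
    return pd.concat(frames, ignore_index=True)


__all__ = [
    "correlation_structure",
    "holdout_validation",
    "sensitivity_compare",
]
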