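"""Pseudo-samples: fully missing future survey waves.

The projection device is to treat a future survey wave as missing data.  A
pseudo-sample is a block of records for a target year in which survey year,
sex and age are fixed — with the age/sex composition matched to an official
population forecast — and every other variable is missing.  After the block
is appended to the observed data, chained-equations imputation fills in the
missing risk factors, effectively extrapolating the fitted time trends.

Cell allocation uses largest-remainder (Hamilton) apportionment so that the
pseudo-sample margins match the forecast *exactly*; sampling cells from a
multinomial instead would add demographic noise to every projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import PROVENANCE, PSEUDO, SchemaError, SurveyTable, VariableSpec


class ForecastError(ValueError):
    """The forecast cannot support the requested pseudo-sample."""


@dataclass
class PopulationForecast:
    """Projected population count per (year, sex, age).

    ``df`` has columns ``year, sex, age, count``; (year, sex, age) must be
    unique and counts non-negative.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["year", "sex", "age", "count"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ForecastError(f"forecast lacks columns {missing}")
        self.df = self.df[required].reset_index(drop=True)
        if (self.df["count"] < 0).any():
            raise ForecastError("forecast counts must be non-negative")
        if self.df.duplicated(["year", "sex", "age"]).any():
            raise ForecastError("duplicate (year, sex, age) in forecast")

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "PopulationForecast":
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)

    def years(self) -> list[int]:
        return sorted(int(y) for y in self.df["year"].unique())

    def cells(self, year: int, age_range: tuple[int, int]) -> pd.DataFrame:
        lo, hi = age_range
        sel = self.df[
            (self.df["year"] == year)
            & (self.df["age"] >= lo)
            & (self.df["age"] <= hi)
        ]
        return sel.copy()


@dataclass(frozen=True)
class PseudoSampleSpec:
    """Target year, number of pseudo-individuals and age bounds."""

    target_year: int
    size: int
    age_range: tuple[int, int] = (25, 64)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("pseudo-sample size must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range bounds out of order")


def allocate_cells(
    forecast: PopulationForecast,
    spec: PseudoSampleSpec,
    sex_order: tuple[str, ...] | None = None,
) -> dict[tuple[str, int], int]:
    """Apportion ``spec.size`` records over (sex, age) forecast cells.

    Largest-remainder integerization: each cell receives the floor of its
    exact quota ``size * count / total``; remaining seats go to the largest
    fractional remainders, ties broken by the lowest cell index after sorting
    cells by (sex order, age).  The returned counts sum exactly to
    ``spec.size``.
    """
    cells = forecast.cells(spec.target_year, spec.age_range)
    if cells.empty or cells["count"].sum() <= 0:
        raise ForecastError(
            f"forecast has no positive counts for year {spec.target_year} "
            f"in ages {spec.age_range}"
        )
    if sex_order is None:
        sex_order = tuple(pd.unique(cells["sex"]))
    rank = {s: i for i, s in enumerate(sex_order)}
    cells = cells.assign(_sex_rank=cells["sex"].map(rank))
    if cells["_sex_rank"].isna().any():
        raise ForecastError("forecast sex labels not in declared sex order")
    cells = cells.sort_values(["_sex_rank", "age"]).reset_index(drop=True)

    counts = cells["count"].to_numpy(dtype=float)
    quota = spec.size * counts / counts.sum()
    floors = np.floor(quota).astype(int)
    seats_left = spec.size - int(floors.sum())
    remainders = quota - floors
    # stable argsort descending: lowest index wins ties
    order = np.argsort(-remainders, kind="stable")
    alloc = floors.copy()
    alloc[order[:seats_left]] += 1

    return {
        (row.sex, int(row.age)): int(a)
        for row, a in zip(cells.itertuples(), alloc)
    }


def build_pseudo_sample(
    spec: PseudoSampleSpec,
    forecast: PopulationForecast,
    schema: list[VariableSpec],
) -> SurveyTable:
    """A fully missing wave for ``spec.target_year``.

    Year, sex and age are fixed per the cell allocation; every other schema
    variable is missing in every record, and all records are flagged as
    pseudo-records.
    """
    sex_spec = next(s for s in schema if s.name == "sex")
    alloc = allocate_cells(forecast, spec, sex_order=sex_spec.levels)
    sexes: list[str] = []
    ages: list[int] = []
    for (sex, age), k in alloc.items():
        sexes.extend([sex] * k)
        ages.extend([age] * k)
    frame = pd.DataFrame(
        {
            "year": float(spec.target_year),
            "sex": sexes,
            "age": np.asarray(ages, dtype=float),
        }
    )
    for s in schema:
        if s.name in ("year", "sex", "age"):
            continue
        frame[s.name] = np.nan if s.vtype != "categorical" else pd.NA
    frame[PROVENANCE] = PSEUDO
    return SurveyTable(frame, schema)


def append_future(
    observed: SurveyTable, pseudo: list[SurveyTable]
) -> SurveyTable:
    """Concatenate observed data with pseudo-waves, keeping provenance."""
    for p in pseudo:
        if not observed.same_schema(p):
            raise SchemaError("pseudo-wave schema differs from observed data")
    if not pseudo:
        return observed.copy()
    df = pd.concat(
        [observed.df] + [p.df for p in pseudo], ignore_index=True
    )
    return SurveyTable(df, list(observed.schema), observed.age_range)


def apply_scenario(
    pseudo: SurveyTable,
    variable: str,
    generator,
    rng: np.random.Generator | None = None,
) -> SurveyTable:
    """Fix an imputable variable in a pseudo-wave to explore a scenario.

    ``generator`` is either a constant value or a distribution: for binary
    variables ``("bernoulli", p)``, for categoricals a mapping level →
    probability.  The engine subsequently treats the variable as observed in
    those records, so the projection answers "what if this covariate were at
    this level".
    """
    spec = pseudo.schema_map.get(variable)
    if spec is None:
        raise SchemaError(f"unknown variable {variable!r}")
    if spec.role == "design" or not spec.imputable:
        raise SchemaError(f"variable {variable!r} is not imputable")
    if not (pseudo.df[PROVENANCE] == PSEUDO).all():
        raise ValueError("apply_scenario expects a pure pseudo-wave")

    out = pseudo.copy()
    n = out.n
    if isinstance(generator, tuple) and generator and generator[0] == "bernoulli":
        if rng is None:
            raise ValueError("a distributional rule needs an rng")
        _, p = generator
        out.df[variable] = (rng.random(n) < p).astype(float)
    elif isinstance(generator, dict):
        if rng is None:
            raise ValueError("a distributional rule needs an rng")
        levels = list(generator)
        probs = np.asarray([generator[k] for k in levels], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("level probabilities must sum to 1")
        idx = rng.choice(len(levels), size=n, p=probs)
        out.df[variable] = [levels[i] for i in idx]
    else:
        out.df[variable] = (
            float(generator) if spec.vtype != "categorical" else generator
        )
    out.validate()
    return out


__all__ = [
    "PopulationForecast",
    "PseudoSampleSpec",
    "ForecastError",
    "allocate_cells",
    "build_pseudo_sample",
    "append_future",
    "apply_scenario",
]
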