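"""Synthetic repeated cross-sectional survey data with known structure.

The national health-examination data this workflow targets (five Finnish
survey waves, 1997–2017) are not publicly deposited, so this module
generates data with the same *shape*: five waves at the published per-sex
sample sizes, ages 25–64, five areas, three education levels, binary
marital status, and binary risk indicators (obesity, current smoking,
hypertension) driven by logit-scale models in sex, age and calendar time.

Two properties make the generator a testing ground rather than a mock:

* every indicator's generating prevalence per (year, sex) is computable
  exactly by enumerating the discrete covariate grid, so recovery tests
  compare against known truth;
* missingness is missing-at-random *by construction* — masking
  probabilities depend only on the always-observed design variables (sex,
  age, year), via per-cell probability tables (calibrated to the published
  per-wave missingness percentages) or logit models.

Continuous BMI / blood-pressure layers exist to exercise the clinical
indicator definitions (BMI >= 30; SBP >= 140 or DBP >= 90 or
antihypertensive medication) but the main fixture draws indicators
directly on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .pseudo import PopulationForecast
from .survey import SurveyTable, finrisk_like_schema


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


AGE_CENTER = 45.0
YEAR_CENTER = 2007.0


@dataclass(frozen=True)
class LogitSpec:
    """Logit-scale model for one binary variable.

    Continuous inputs are centered and decade-scaled: the ``age``
    coefficient is per decade of age around 45, ``year`` per decade around
    2007.  ``wave_shift`` adds a per-calendar-year offset, used e.g. to
    engineer an abrupt level change in one wave.
    """

    intercept: float
    male: float = 0.0
    age: float = 0.0
    year: float = 0.0
    age_x_year: float = 0.0
    year_sq: float = 0.0
    education: tuple[float, float] = (0.0, 0.0)  # levels 2, 3 vs reference
    marital: float = 0.0
    wave_shift: tuple[tuple[int, float], ...] = ()

    def eta(self, is_male, age, year, edu_code=0, marital=0):
        a = (np.asarray(age, dtype=float) - AGE_CENTER) / 10.0
        t = (np.asarray(year, dtype=float) - YEAR_CENTER) / 10.0
        edu_code = np.asarray(edu_code)
        out = (
            self.intercept
            + self.male * np.asarray(is_male, dtype=float)
            + self.age * a
            + self.year * t
            + self.age_x_year * a * t
            + self.year_sq * t**2
            + np.where(edu_code == 1, self.education[0], 0.0)
            + np.where(edu_code == 2, self.education[1], 0.0)
            + self.marital * np.asarray(marital, dtype=float)
        )
        for yr, shift in self.wave_shift:
            out = out + np.where(np.asarray(year) == yr, shift, 0.0)
        return out


@dataclass(frozen=True)
class MissingnessSpec:
    """MAR masking rule for one variable.

    Either a probability ``table`` keyed by (sex label, year) or a
    ``logit`` model in (male, age, year) on the same centered/decade
    scales as :class:`LogitSpec`.  Only design variables may appear —
    that restriction is what makes the fixture MAR by construction.
    """

    table: tuple[tuple[tuple[str, int], float], ...] | None = None
    logit: tuple[float, float, float, float] | None = None  # b0, male, age, year

    def __post_init__(self) -> None:
        if (self.table is None) == (self.logit is None):
            raise ConfigError("give exactly one of table / logit")
        if self.table is not None:
            for _, p in self.table:
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"masking probability {p} outside [0, 1]")

    def prob(self, sex_label, is_male, age, year) -> np.ndarray:
        if self.table is not None:
            lookup = dict(self.table)
            sex_label = np.asarray(sex_label)
            year = np.asarray(year)
            out = np.empty(sex_label.shape, dtype=float)
            for i in range(out.size):
                key = (sex_label.flat[i], int(year.flat[i]))
                if key not in lookup:
                    raise ConfigError(f"no masking probability for cell {key}")
                out.flat[i] = lookup[key]
            return out
        b0, bm, ba, by = self.logit
        a = (np.asarray(age, dtype=float) - AGE_CENTER) / 10.0
        t = (np.asarray(year, dtype=float) - YEAR_CENTER) / 10.0
        return expit(b0 + bm * np.asarray(is_male, dtype=float) + ba * a + by * t)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    waves: tuple[tuple[int, int, int], ...]  # (year, n invited men, n women)
    indicators: tuple[tuple[str, LogitSpec], ...]
    missingness: tuple[tuple[str, MissingnessSpec], ...] = ()
    age_range: tuple[int, int] = (25, 64)
    sex_levels: tuple[str, str] = ("male", "female")
    include_covariates: bool = True
    n_areas: int = 5

    def __post_init__(self) -> None:
        years = [w[0] for w in self.waves]
        if years != sorted(set(years)):
            raise ConfigError("wave years must be strictly increasing")
        names = {name for name, _ in self.indicators}
        for name, _ in self.missingness:
            if name in ("year", "sex", "age"):
                raise ConfigError("design variables cannot be masked")
        del names

    def schema(self):
        return finrisk_like_schema(
            sex_levels=self.sex_levels,
            n_areas=self.n_areas,
            indicators=tuple(name for name, _ in self.indicators),
            include_covariates=self.include_covariates,
        )

    def indicator_map(self) -> dict[str, LogitSpec]:
        return dict(self.indicators)


# -- default study conditions ------------------------------------------------

#: published per-wave invited sample sizes (year, men, women)
TABLE_SIZES = (
    (1997, 5000, 5000),
    (2002, 4999, 5000),
    (2007, 4000, 4000),
    (2012, 4000, 4000),
    (2017, 1635, 1542),
)

#: published per-wave missingness fractions, (variable, sex) -> year -> pct
_MISSING_PCT = {
    ("obesity", "male"): (32.1, 40.6, 44.0, 48.5, 48.1),
    ("obesity", "female"): (24.8, 30.0, 34.4, 40.3, 38.3),
    ("smoking", "male"): (32.6, 35.3, 40.0, 43.5, 42.6),
    ("smoking", "female"): (25.2, 25.0, 29.8, 33.9, 31.9),
    ("hypertension", "male"): (32.1, 40.4, 43.4, 47.6, 46.7),
    ("hypertension", "female"): (24.8, 29.5, 33.7, 39.1, 37.1),
}


def _table_spec(variable: str) -> MissingnessSpec:
    years = [w[0] for w in TABLE_SIZES]
    entries = []
    for sex in ("male", "female"):
        for year, pct in zip(years, _MISSING_PCT[(variable, sex)]):
            entries.append(((sex, year), pct / 100.0))
    return MissingnessSpec(table=tuple(entries))


def default_config() -> GeneratorConfig:
    """Five waves at the published sizes and missingness rates.

    Indicator models are chosen to resemble the published prevalence levels
    and trends: obesity rising (with a year-by-age interaction), smoking
    falling with curvature, hypertension high, strongly age-graded and
    slowly falling.
    """
    indicators = (
        ("obesity", LogitSpec(
            intercept=-1.40, male=0.05, age=0.25, year=0.18, age_x_year=0.06,
            education=(-0.15, -0.35), marital=0.05,
        )),
        ("smoking", LogitSpec(
            intercept=-1.35, male=0.45, age=-0.15, year=-0.30, year_sq=-0.10,
            education=(-0.30, -0.70), marital=-0.20,
        )),
        ("hypertension", LogitSpec(
            intercept=-0.80, male=0.60, age=0.95, year=-0.12,
            education=(-0.10, -0.20), marital=0.10,
        )),
    )
    covariate_missing = MissingnessSpec(logit=(-2.1, 0.35, 0.0, 0.25))
    missingness = tuple(
        (name, _table_spec(name)) for name, _ in indicators
    ) + (
        ("area", covariate_missing),
        ("education", covariate_missing),
        ("marital", covariate_missing),
    )
    return GeneratorConfig(
        waves=TABLE_SIZES, indicators=indicators, missingness=missingness
    )


def linear_trend_config(
    n_per_wave: int = 1000,
    years: tuple[int, ...] = (1997, 2002, 2007, 2012, 2017),
    trend: float = 0.35,
    wave_shift: tuple[tuple[int, float], ...] = (),
) -> GeneratorConfig:
    """Reduced-scale conditions: one indicator, linear logit-scale trend.

    Used for recovery and calibration studies: minimal schema (design
    variables + one indicator), MAR missingness depending on sex, age and
    year.
    """
    spec = LogitSpec(
        intercept=-1.0, male=0.30, age=0.30, year=trend, wave_shift=wave_shift
    )
    return GeneratorConfig(
        waves=tuple((y, n_per_wave, n_per_wave) for y in years),
        indicators=(("risk", spec),),
        missingness=(("risk", MissingnessSpec(logit=(-1.2, 0.40, 0.15, 0.30))),),
        include_covariates=False,
    )


# -- covariate model (fixed, discrete, enumerable) ---------------------------


def _area_probs(n_areas: int) -> np.ndarray:
    base = np.array([0.25, 0.20, 0.20, 0.20, 0.15][:n_areas], dtype=float)
    if base.size < n_areas:
        base = np.full(n_areas, 1.0 / n_areas)
    return base / base.sum()


def _edu_probs(age: np.ndarray) -> np.ndarray:
    """P(basic, secondary, higher) by age: younger cohorts more educated."""
    young = np.asarray(age) < 45
    out = np.where(
        young[..., None],
        np.array([0.20, 0.35, 0.45]),
        np.array([0.35, 0.35, 0.30]),
    )
    return out


def _marital_prob(age: np.ndarray) -> np.ndarray:
    return expit(-1.0 + 0.06 * (np.asarray(age, dtype=float) - 25.0))


# -- generation --------------------------------------------------------------


def generate_population(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[SurveyTable, pd.DataFrame]:
    """Draw a fully observed survey table plus its ground-truth table.

    Returns ``(table, truth)`` where ``truth`` has one row per
    (indicator, year, sex) with the exact generating prevalence obtained by
    enumerating the discrete covariate grid.
    """
    frames = []
    schema = config.schema()
    lo, hi = config.age_range
    male_label, female_label = config.sex_levels
    edu_levels = ("basic", "secondary", "higher")
    for year, n_m, n_w in config.waves:
        for sex, n in ((male_label, n_m), (female_label, n_w)):
            is_male = float(sex == male_label)
            age = rng.integers(lo, hi + 1, size=n).astype(float)
            rec = {"year": float(year), "sex": sex, "age": age}
            edu_code = np.zeros(n, dtype=int)
            marital = np.zeros(n)
            if config.include_covariates:
                rec["area"] = rng.choice(
                    [f"area{i + 1}" for i in range(config.n_areas)],
                    size=n, p=_area_probs(config.n_areas),
                )
                probs = _edu_probs(age)
                u = rng.random(n)
                edu_code = (u > probs[:, 0]).astype(int) + (
                    u > probs[:, 0] + probs[:, 1]
                ).astype(int)
                rec["education"] = np.array(edu_levels)[edu_code]
                marital = (rng.random(n) < _marital_prob(age)).astype(float)
                rec["marital"] = marital
            for name, spec in config.indicators:
                p = expit(spec.eta(is_male, age, year, edu_code, marital))
                rec[name] = (rng.random(n) < p).astype(float)
            frames.append(pd.DataFrame(rec))
    table = SurveyTable(
        pd.concat(frames, ignore_index=True), schema, config.age_range
    )
    truth = truth_table(config)
    return table, truth


def truth_prevalence(
    config: GeneratorConfig,
    indicator: str,
    year: int,
    sex: str,
    age_weights: dict[int, float] | None = None,
) -> float:
    """Exact generating prevalence by enumerating the covariate grid.

    ``age_weights`` reweights the (integer) age distribution — pass a
    forecast's age composition to get the truth a forecast-matched
    pseudo-sample targets; the default is the generator's uniform ages.
    """
    spec = config.indicator_map()[indicator]
    lo, hi = config.age_range
    ages = np.arange(lo, hi + 1, dtype=float)
    if age_weights is None:
        w_age = np.full(ages.size, 1.0 / ages.size)
    else:
        w_age = np.array([age_weights.get(int(a), 0.0) for a in ages])
        total = w_age.sum()
        if total <= 0:
            raise ConfigError("age weights sum to zero over the age range")
        w_age = w_age / total
    is_male = float(sex == config.sex_levels[0])

    if not config.include_covariates:
        p = expit(spec.eta(is_male, ages, year))
        return float(p @ w_age)

    edu = _edu_probs(ages)  # (n_age, 3)
    pm = _marital_prob(ages)
    total_p = np.zeros(ages.size)
    for e in range(3):
        for mar, w_mar in ((0.0, 1.0 - pm), (1.0, pm)):
            p = expit(spec.eta(is_male, ages, year, e, mar))
            total_p += edu[:, e] * w_mar * p
    return float(total_p @ w_age)


def truth_table(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for name, _ in config.indicators:
        for year, _, _ in config.waves:
            for sex in config.sex_levels:
                rows.append(
                    {
                        "indicator": name,
                        "year": year,
                        "sex": sex,
                        "prevalence": truth_prevalence(config, name, year, sex),
                    }
                )
    return pd.DataFrame(rows)


def impose_missingness(
    table: SurveyTable, config: GeneratorConfig, rng: np.random.Generator
) -> SurveyTable:
    """Mask cells per the MAR missingness model; design variables untouched."""
    out = table.copy()
    df = out.df
    male_label = config.sex_levels[0]
    is_male = (df["sex"] == male_label).to_numpy(dtype=float)
    for name, spec in config.missingness:
        if name not in out.schema_map:
            raise ConfigError(f"missingness names unknown variable {name!r}")
        if out.schema_map[name].role == "design":
            raise ConfigError(f"design variable {name!r} cannot be masked")
        p = spec.prob(
            df["sex"].to_numpy(), is_male, df["age"].to_numpy(),
            df["year"].to_numpy(),
        )
        mask = rng.random(len(df)) < p
        df.loc[mask, name] = np.nan
    out.validate()
    return out


def generate_survey(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[SurveyTable, pd.DataFrame]:
    """Convenience: population draw followed by MAR masking."""
    table, truth = generate_population(config, rng)
    return impose_missingness(table, config, rng), truth


# -- clinical indicator definitions ------------------------------------------


def derive_indicators(bmi, sbp, dbp, bp_medication):
    """Clinical definitions: obesity = BMI >= 30; hypertension = SBP >= 140
    or DBP >= 90 or current antihypertensive medication."""
    bmi = np.asarray(bmi, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(bp_medication, dtype=bool)
    obesity = (bmi >= 30.0).astype(float)
    hypertension = ((sbp >= 140.0) | (dbp >= 90.0) | med).astype(float)
    return obesity, hypertension


def generate_continuous(
    age, is_male, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Plausible measured BMI / blood pressure / medication layer."""
    age = np.asarray(age, dtype=float)
    n = age.size
    a = (age - AGE_CENTER) / 10.0
    bmi = rng.normal(26.3 + 0.45 * a + 0.3 * is_male, 4.2, size=n)
    sbp = rng.normal(127.0 + 6.5 * a + 4.0 * is_male, 16.0, size=n)
    dbp = rng.normal(79.0 + 2.5 * a + 2.5 * is_male, 10.0, size=n)
    med = rng.random(n) < expit(-3.2 + 1.1 * a)
    return {"bmi": bmi, "sbp": sbp, "dbp": dbp, "bp_medication": med}


# -- population forecast ------------------------------------------------------


def make_forecast(
    config: GeneratorConfig,
    future_years: list[int],
    growth_rule=None,
) -> PopulationForecast:
    """Forecast table from a smooth baseline age pyramid.

    ``growth_rule(year, sex, age) -> multiplier`` reshapes the pyramid per
    year (e.g. to shift mass toward older ages); the identity rule keeps
    future margins equal to the baseline.
    """
    last_wave = config.waves[-1][0]
    for y in future_years:
        if y <= last_wave:
            raise ConfigError(
                f"forecast year {y} not after the last wave {last_wave}"
            )
    lo, hi = config.age_range
    ages = np.arange(lo, hi + 1)
    rows = []
    for year in future_years:
        for sex, mu in zip(config.sex_levels, (42.0, 44.0)):
            base = 1000.0 * np.exp(-0.5 * ((ages - mu) / 15.0) ** 2)
            for age, count in zip(ages, base):
                mult = 1.0 if growth_rule is None else float(
                    growth_rule(year, sex, int(age))
                )
                if mult < 0:
                    raise ConfigError("growth multiplier must be >= 0")
                rows.append(
                    {"year": year, "sex": sex, "age": int(age),
                     "count": count * mult}
                )
    return PopulationForecast(pd.DataFrame(rows))


def forecast_age_weights(
    forecast: PopulationForecast, year: int, sex: str,
    age_range: tuple[int, int],
) -> dict[int, float]:
    """Normalized age distribution of one forecast (year, sex) margin."""
    cells = forecast.cells(year, age_range)
    cells = cells[cells["sex"] == sex]
    total = cells["count"].sum()
    return {int(r.age): float(r.count / total) for r in cells.itertuples()}


__all__ = [
    "LogitSpec",
    "MissingnessSpec",
    "GeneratorConfig",
    "ConfigError",
    "TABLE_SIZES",
    "default_config",
    "linear_trend_config",
    "generate_population",
    "generate_survey",
    "impose_missingness",
    "truth_prevalence",
    "truth_table",
    "derive_indicators",
    "generate_continuous",
    "make_forecast",
    "forecast_age_weights",
]
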