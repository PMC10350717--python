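"""Schema-validated survey tables with delimited-text I/O.

Repeated cross-sectional health-examination surveys are represented as a
rectangular table with one record per *invited* individual.  Three design
variables (survey ``year``, ``sex``, ``age``) are always observed; risk-factor
indicators and sociodemographic covariates may be missing because of unit
non-response or item non-response, and both kinds of missingness are treated
identically (a missing cell is a missing cell).

Internally a :class:`SurveyTable` wraps a :class:`pandas.DataFrame`:

* binary and continuous variables are stored as floats with ``NaN`` for
  missing;
* categorical variables are stored as strings (``NaN`` for missing) and are
  validated against their declared level sets.

A hidden provenance column records whether each record was actually surveyed
(``"observed"``) or is a fully missing pseudo-record for a future wave
(``"pseudo"``); downstream fitting code uses it to keep model-fitting sets
restricted to genuinely observed outcomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("outcome", "covariate", "design")
VTYPES = ("binary", "categorical", "continuous")

#: name of the hidden provenance column
PROVENANCE = "_source"
OBSERVED = "observed"
PSEUDO = "pseudo"

#: tokens interpreted as missing on read
MISSING_TOKENS = ("", "NA")


class SchemaError(ValueError):
    """A column required by the schema is absent or a spec is inconsistent."""


class ValidationError(ValueError):
    """A cell value violates the schema (level set, missing design value...)."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one survey variable.

    Parameters
    ----------
    name:
        Column name in the delimited file.
    role:
        ``"design"`` (year / sex / age — never missing, never imputed),
        ``"covariate"`` or ``"outcome"``.
    vtype:
        ``"binary"`` (coded 0/1), ``"categorical"`` (string levels) or
        ``"continuous"``.
    levels:
        Ordered level labels; required for categorical variables, ignored
        otherwise.  The first level is the reference level in dummy coding.
    imputable:
        Whether the chained-equations engine may fill missing values of this
        variable.  Design variables are never imputable.
    """

    name: str
    role: str
    vtype: str
    levels: tuple[str, ...] | None = None
    imputable: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.vtype not in VTYPES:
            raise SchemaError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.vtype == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise SchemaError(
                    f"categorical variable {self.name!r} needs >= 2 levels"
                )
            object.__setattr__(self, "levels", tuple(self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"duplicate levels for {self.name!r}")
        elif self.levels is not None:
            if len(self.levels) != 2:
                raise SchemaError(
                    f"binary variable {self.name!r} must have exactly 2 levels"
                )
            object.__setattr__(self, "levels", tuple(self.levels))
        if self.role == "design" and self.imputable:
            raise SchemaError(f"design variable {self.name!r} cannot be imputable")


def finrisk_like_schema(
    sex_levels: tuple[str, str] = ("male", "female"),
    n_areas: int = 5,
    education_levels: tuple[str, ...] = ("basic", "secondary", "higher"),
    indicators: tuple[str, ...] = ("obesity", "smoking", "hypertension"),
    include_covariates: bool = True,
) -> list[VariableSpec]:
    """Schema shaped like five Finnish health-examination survey waves.

    Ages 25–64, five geographical areas, three education levels, binary
    marital status and binary risk-factor indicators (obesity, current
    smoking, hypertension).
    """
    schema = [
        VariableSpec("year", "design", "continuous"),
        VariableSpec("sex", "design", "categorical", levels=tuple(sex_levels)),
        VariableSpec("age", "design", "continuous"),
    ]
    if include_covariates:
        areas = tuple(f"area{i + 1}" for i in range(n_areas))
        schema += [
            VariableSpec("area", "covariate", "categorical", levels=areas,
                         imputable=True),
            VariableSpec("education", "covariate", "categorical",
                         levels=tuple(education_levels), imputable=True),
            VariableSpec("marital", "covariate", "binary", imputable=True),
        ]
    schema += [
        VariableSpec(name, "outcome", "binary", imputable=True)
        for name in indicators
    ]
    return schema


@dataclass
class SurveyTable:
    """A validated survey table (records × schema variables).

    ``df`` holds one column per schema variable plus, optionally, the
    provenance column :data:`PROVENANCE`.
    """

    df: pd.DataFrame
    schema: list[VariableSpec] = field(default_factory=list)
    age_range: tuple[int, int] | None = None

    # -- construction -----------------------------------------------------
    def __post_init__(self) -> None:
        self.schema = list(self.schema)
        by_name = self.schema_map
        missing_cols = [s.name for s in self.schema if s.name not in self.df.columns]
        if missing_cols:
            raise SchemaError(f"schema columns absent from data: {missing_cols}")
        if PROVENANCE not in self.df.columns:
            self.df = self.df.copy()
            self.df[PROVENANCE] = OBSERVED
        order = [s.name for s in self.schema] + [PROVENANCE]
        self.df = self.df[order].reset_index(drop=True)
        for spec in self.schema:
            if spec.vtype in ("binary", "continuous"):
                self.df[spec.name] = pd.to_numeric(self.df[spec.name]).astype(float)
        self.validate()
        del by_name

    @property
    def schema_map(self) -> dict[str, VariableSpec]:
        return {s.name: s for s in self.schema}

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def waves(self) -> list[int]:
        """Distinct survey years, ascending."""
        return sorted(int(y) for y in self.df["year"].dropna().unique())

    def validate(self) -> None:
        df, by_name = self.df, self.schema_map
        for name in ("year", "sex", "age"):
            if name not in by_name:
                raise SchemaError(f"design variable {name!r} missing from schema")
            if df[name].isna().any():
                bad = int(df[name].isna().idxmax())
                raise ValidationError(
                    f"design variable {name!r} missing in row {bad}"
                )
        for spec in self.schema:
            col = df[spec.name]
            if spec.vtype == "categorical":
                values = col.dropna()
                bad = ~values.isin(spec.levels)
                if bad.any():
                    row = int(bad.idxmax())
                    raise ValidationError(
                        f"value {values[row]!r} of {spec.name!r} in row {row} "
                        f"not in levels {spec.levels}"
                    )
            elif spec.vtype == "binary":
                values = col.dropna()
                if not values.isin((0.0, 1.0)).all():
                    bad = values[~values.isin((0.0, 1.0))]
                    row = int(bad.index[0])
                    raise ValidationError(
                        f"binary variable {spec.name!r} has non-0/1 value "
                        f"{bad.iloc[0]!r} in row {row}"
                    )
        if self.age_range is not None and len(df):
            lo, hi = self.age_range
            ages = df["age"]
            if ((ages < lo) | (ages > hi)).any():
                raise ValidationError(f"age outside [{lo}, {hi}]")
        src = df[PROVENANCE]
        if not src.isin((OBSERVED, PSEUDO)).all():
            raise ValidationError("provenance column must be 'observed'/'pseudo'")

    # -- convenience ------------------------------------------------------
    def imputable_variables(self) -> list[str]:
        return [s.name for s in self.schema if s.imputable]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing cells over schema columns."""
        return self.df[[s.name for s in self.schema]].isna()

    def copy(self) -> "SurveyTable":
        return SurveyTable(self.df.copy(), list(self.schema), self.age_range)

    def same_schema(self, other: "SurveyTable") -> bool:
        return self.schema == other.schema


# ---------------------------------------------------------------------------
# delimited-text I/O


def load_survey(
    path,
    schema: list[VariableSpec],
    sep: str = ",",
    missing_tokens: tuple[str, ...] = MISSING_TOKENS,
    age_range: tuple[int, int] | None = None,
) -> SurveyTable:
    """Read a delimited text file into a validated :class:`SurveyTable`.

    Unknown columns are ignored with a logged warning; an absent schema
    column raises :class:`SchemaError`; out-of-level values raise
    :class:`ValidationError` naming the offending row and value.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    known = {s.name for s in schema} | {PROVENANCE}
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown columns %s in %s", unknown, path)
    absent = [s.name for s in schema if s.name not in raw.columns]
    if absent:
        raise SchemaError(f"file {path} lacks schema columns {absent}")

    cols: dict[str, object] = {}
    for spec in schema:
        col = raw[spec.name].where(~raw[spec.name].isin(missing_tokens), np.nan)
        if spec.vtype in ("binary", "continuous"):
            try:
                col = pd.to_numeric(col)
            except (ValueError, TypeError) as exc:
                raise ValidationError(
                    f"non-numeric value in column {spec.name!r}: {exc}"
                ) from exc
        cols[spec.name] = col
    frame = pd.DataFrame(cols)
    if PROVENANCE in raw.columns:
        frame[PROVENANCE] = raw[PROVENANCE]
    return SurveyTable(frame, schema, age_range)


def write_survey(
    table: SurveyTable, path, sep: str = ",", missing_token: str = ""
) -> None:
    """Write a survey table as delimited text (header row, stable order)."""
    out = table.df.copy()
    for spec in table.schema:
        if spec.vtype in ("binary", "continuous"):
            col = out[spec.name]
            if col.dropna().mod(1).eq(0).all():
                out[spec.name] = col.map(
                    lambda v: "" if pd.isna(v) else str(int(v))
                )
    out.to_csv(path, sep=sep, index=False, na_rep=missing_token)


# ---------------------------------------------------------------------------
# missingness summaries


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


def missingness_summary(
    table: SurveyTable, variables: list[str] | None = None
) -> pd.DataFrame:
    """Missing counts and percentages per variable × wave × sex.

    Mirrors the usual survey-report presentation: the denominator is the
    entire invited sample in the cell, and the percentage is rounded half-up
    to one decimal.
    """
    by_name = table.schema_map
    if variables is None:
        variables = table.imputable_variables()
    for v in variables:
        if v not in by_name:
            raise SchemaError(f"unknown variable {v!r}")
    rows = []
    df = table.df
    for (year, sex), cell in df.groupby(["year", "sex"], sort=True):
        n = len(cell)
        for v in variables:
            miss = int(cell[v].isna().sum())
            rows.append(
                {
                    "variable": v,
                    "year": int(year),
                    "sex": sex,
                    "n_invited": n,
                    "n_missing": miss,
                    "pct_missing": _round_half_up(100.0 * miss / n),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["variable", "year", "sex", "n_invited", "n_missing",
                 "pct_missing"],
    )
    return out.sort_values(["variable", "year", "sex"]).reset_index(drop=True)


__all__ = [
    "VariableSpec",
    "SurveyTable",
    "SchemaError",
    "ValidationError",
    "finrisk_like_schema",
    "load_survey",
    "write_survey",
    "missingness_summary",
    "PROVENANCE",
    "OBSERVED",
    "PSEUDO",
]
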