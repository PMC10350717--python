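"""Rubin's rules: pooling prevalences across imputed datasets.

Each completed dataset yields a prevalence estimate q_i for a cell (say,
men in 2025) with within-imputation variance w_i = q_i (1 - q_i) / n.
Rubin's rules combine the m estimates:

    Qbar = mean(q_i)                     pooled estimate
    Wbar = mean(w_i)                     mean within-imputation variance
    B    = sum (q_i - Qbar)^2 / (m - 1)  between-imputation variance
    T    = Wbar + (1 + 1/m) B            total variance
    nu   = (m - 1) (1 + Wbar / ((1 + 1/m) B))^2   degrees of freedom

with a t_nu confidence interval Qbar ± t * sqrt(T), truncated to [0, 1].
When B = 0 (identical estimates across imputations) the normal quantile is
used.  The between component is what carries the projection uncertainty:
for a fully imputed future wave it reflects parameter uncertainty of the
imputation models propagated through the draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mice import ImputedStack
from .survey import SurveyTable


@dataclass(frozen=True)
class PerDatasetEstimate:
    """Prevalence and Wald within-variance from one completed dataset."""

    q: float
    w: float
    n_cell: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"prevalence {self.q} outside [0, 1]")
        if self.w < 0:
            raise ValueError("within-imputation variance must be >= 0")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules quantities and confidence interval for one prevalence."""

    q_bar: float
    w_bar: float
    b: float
    t: float
    df: float
    level: float
    ci: tuple[float, float]
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t))


def _select(df: pd.DataFrame, cell: dict) -> pd.Series:
    mask = pd.Series(True, index=df.index)
    for col, rule in cell.items():
        if isinstance(rule, tuple):
            lo, hi = rule
            mask &= (df[col] >= lo) & (df[col] <= hi)
        else:
            mask &= df[col] == rule
    return mask


def cell_prevalence(
    dataset: SurveyTable, indicator: str, cell: dict
) -> PerDatasetEstimate:
    """Prevalence of a binary indicator in a cell of one completed dataset.

    ``cell`` maps column names to either an exact value (``{"year": 2025,
    "sex": "male"}``) or an inclusive ``(lo, hi)`` range for age groups.
    """
    spec = dataset.schema_map.get(indicator)
    if spec is None or spec.vtype != "binary":
        raise ValueError(f"{indicator!r} is not a binary schema variable")
    mask = _select(dataset.df, cell)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty cell for selection {cell!r}")
    values = pd.to_numeric(dataset.df.loc[mask, indicator]).to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"cell contains missing {indicator!r} values")
    q = float(values.mean())
    w = q * (1.0 - q) / n
    return PerDatasetEstimate(q=q, w=w, n_cell=n)


def rubin_pool(
    estimates: list[PerDatasetEstimate], level: float = 0.95
) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules."""
    m = len(estimates)
    if m < 2:
        raise ValueError("Rubin's rules need m >= 2 estimates")
    q = np.array([e.q for e in estimates])
    w = np.array([e.w for e in estimates])
    q_bar = float(q.mean())
    w_bar = float(w.mean())
    b = float(((q - q_bar) ** 2).sum() / (m - 1))
    t = w_bar + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b)) ** 2
        quant = float(stats.t.ppf(0.5 * (1.0 + level), df))
    else:
        df = float("inf")
        quant = float(stats.norm.ppf(0.5 * (1.0 + level)))
    half = quant * float(np.sqrt(t))
    ci = (max(0.0, q_bar - half), min(1.0, q_bar + half))
    return PooledEstimate(
        q_bar=q_bar, w_bar=w_bar, b=b, t=float(t), df=float(df),
        level=level, ci=ci, m=m,
    )


def project_prevalences(
    stack: ImputedStack,
    indicator: str,
    groups: list[dict],
    level: float = 0.95,
) -> pd.DataFrame:
    """Pooled prevalence with CI for each group over the imputed stack.

    Groups are cell selections (typically year × sex); observed waves give
    pooled estimates too, since their missing cells were also imputed.
    Returns a tidy table with estimate, se, CI bounds, m and df.
    """
    if not groups:
        raise ValueError("no groups requested")
    rows = []
    for cell in groups:
        ests = [cell_prevalence(ds, indicator, cell) for ds in stack.datasets]
        pooled = rubin_pool(ests, level=level)
        row = {f"{k}": (v if not isinstance(v, tuple) else f"{v[0]}-{v[1]}")
               for k, v in cell.items()}
        row.update(
            indicator=indicator,
            estimate=pooled.q_bar,
            se=pooled.se,
            ci_low=pooled.ci[0],
            ci_high=pooled.ci[1],
            m=pooled.m,
            df=pooled.df,
            n_cell=ests[0].n_cell,
        )
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "PerDatasetEstimate",
    "PooledEstimate",
    "cell_prevalence",
    "rubin_pool",
    "project_prevalences",
]
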