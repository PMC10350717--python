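"""Restricted cubic splines (natural splines, truncated-power form).

A restricted cubic spline with knots t1 < ... < tk is a piecewise cubic that
is constrained to be *linear* beyond the boundary knots.  That tail
linearity is exactly what makes the spline safe for extrapolating a survey
time trend to future years: beyond the last observed wave the fitted trend
continues as a straight line on the logit scale instead of blowing up like
an unconstrained cubic.

With k knots the basis has one linear column plus k-2 nonlinear columns

    f_j(x) = [ (x-t_j)+^3
               - (x-t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
               + (x-t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2

for j = 1..k-2, so "df" degrees of freedom means k = df + 1 knots.  Knots
are placed at the conventional Harrell quantiles of the distinct values
(0.10/0.50/0.90 for three knots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default knot-placement quantiles, per number of knots
HARRELL_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.5, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class RCSBasis:
    """Frozen knot locations for a restricted cubic spline."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(t) for t in self.knots)
        if len(knots) < 3:
            raise ValueError("a restricted cubic spline needs >= 3 knots")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing: {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    @property
    def n_nonlinear(self) -> int:
        return len(self.knots) - 2


def rcs_basis(values, df: int) -> RCSBasis:
    """Choose knots from a continuous sample for a spline with ``df`` dof.

    Knots sit at the Harrell default quantiles of the *distinct* values, so
    repeated survey years do not drag knots toward the big waves.
    """
    if df < 2:
        raise ValueError("spline df must be >= 2")
    k = df + 1
    distinct = np.unique(np.asarray(values, dtype=float))
    distinct = distinct[~np.isnan(distinct)]
    if distinct.size < k:
        raise ValueError(
            f"need at least {k} distinct values for {k} knots, "
            f"got {distinct.size}"
        )
    if k in HARRELL_QUANTILES:
        probs = HARRELL_QUANTILES[k]
    else:  # equally spaced interior coverage for unusual k
        probs = tuple(np.linspace(0.05, 0.95, k))
    knots = np.quantile(distinct, probs)
    if np.any(np.diff(knots) <= 0):  # fall back to evenly indexed distinct values
        idx = np.linspace(0, distinct.size - 1, k).round().astype(int)
        knots = distinct[idx]
    return RCSBasis(tuple(knots))


def rcs_transform(basis: RCSBasis, x) -> np.ndarray:
    """Evaluate the spline basis: column 0 is x, then k-2 nonlinear terms.

    Returns an array of shape ``(n, k - 1)``.  Each nonlinear term is zero
    below the first knot and exactly linear above the last.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(basis.knots)
    k = t.size
    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        d = _pos_cube(x - t[j])
        d -= _pos_cube(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
        d += _pos_cube(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        cols.append(d / scale)
    return np.column_stack(cols)


def _pos_cube(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, 0.0) ** 3


__all__ = ["RCSBasis", "rcs_basis", "rcs_transform", "HARRELL_QUANTILES"]
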