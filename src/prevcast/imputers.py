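"""Conditional imputation models and BIC-based model selection.

Two imputer families cover the survey schema:

* **binary logistic** ("logreg" in the chained-equations tradition) — a
  lightly ridge-penalized logistic regression fitted by IRLS; imputations
  are *proper*: a parameter vector is drawn from the asymptotic normal
  approximation MVN(beta_hat, V_hat) before Bernoulli draws, so repeated
  imputations carry parameter uncertainty into the between-imputation
  variance.
* **polytomous logistic** ("polyreg") — a multinomial logistic model refit
  on a bootstrap resample of the fitting records for each set of draws; the
  bootstrap plays the role of the parameter draw, which is easier to keep
  numerically stable than a multinomial posterior approximation.

Predictor structure is declared as a list of :class:`TermSpec` — main
effects, interactions and restricted-cubic-spline terms — and a forward
stepwise search over candidate terms picks the model minimizing the
Bayesian information criterion, BIC = k ln(n) - 2 log L.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .splines import RCSBasis, rcs_basis, rcs_transform
from .survey import OBSERVED, PROVENANCE, SurveyTable, VariableSpec


class DegenerateOutcomeError(ValueError):
    """The outcome shows a single level among fitting records."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# model terms and design matrices


@dataclass(frozen=True)
class TermSpec:
    """One predictor term: a main effect, interaction or spline."""

    kind: str  # "main" | "interaction" | "spline"
    variables: tuple[str, ...]
    spline_df: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.kind not in ("main", "interaction", "spline"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "interaction" and len(self.variables) < 2:
            raise ValueError("interaction needs >= 2 variables")
        if self.kind == "spline":
            if len(self.variables) != 1:
                raise ValueError("spline applies to one variable")
            if self.spline_df is None or self.spline_df < 2:
                raise ValueError("spline df must be >= 2")
        elif self.kind == "main" and len(self.variables) != 1:
            raise ValueError("main effect takes one variable")

    def label(self) -> str:
        if self.kind == "spline":
            return f"rcs({self.variables[0]},{self.spline_df})"
        return ":".join(self.variables)


def main(var: str) -> TermSpec:
    return TermSpec("main", (var,))


def interaction(*vars: str) -> TermSpec:
    return TermSpec("interaction", tuple(vars))


def spline(var: str, df: int = 2) -> TermSpec:
    return TermSpec("spline", (var,), spline_df=df)


@dataclass(frozen=True)
class ImputationModel:
    """Conditional model for one imputable variable."""

    outcome: str
    terms: tuple[TermSpec, ...]
    family: str  # "binary-logistic" | "polytomous-logistic"
    ridge: float = 1e-5

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        for t in self.terms:
            if self.outcome in t.variables:
                raise ValueError(
                    f"outcome {self.outcome!r} cannot appear among predictors"
                )
        if self.family not in ("binary-logistic", "polytomous-logistic"):
            raise ValueError(f"unknown family {self.family!r}")

    def predictor_variables(self) -> set[str]:
        return {v for t in self.terms for v in t.variables}


def _encode(df: pd.DataFrame, spec: VariableSpec) -> tuple[np.ndarray, list[str]]:
    """Numeric encoding of one variable: dummy-coded if categorical."""
    col = df[spec.name]
    if spec.vtype == "categorical":
        codes = pd.Categorical(col, categories=spec.levels).codes
        out = np.empty((len(df), len(spec.levels) - 1))
        for j in range(1, len(spec.levels)):
            out[:, j - 1] = (codes == j).astype(float)
        out[codes == -1] = np.nan
        names = [f"{spec.name}[{lv}]" for lv in spec.levels[1:]]
        return out, names
    values = pd.to_numeric(col).to_numpy(dtype=float).reshape(-1, 1)
    return values, [spec.name]


def build_design(
    df: pd.DataFrame,
    terms: tuple[TermSpec, ...] | list[TermSpec],
    schema_map: dict[str, VariableSpec],
    spline_bases: dict[str, RCSBasis] | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build the model matrix for a term list.

    Returns ``(X, names, complete)`` where ``X`` has an intercept as its
    first column and ``complete`` flags rows with no missing value in any
    predictor.
    """
    spline_bases = spline_bases or {}
    n = len(df)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["(Intercept)"]
    for term in terms:
        if term.kind == "main":
            block, bn = _encode(df, schema_map[term.variables[0]])
        elif term.kind == "spline":
            var = term.variables[0]
            basis = spline_bases.get(var)
            if basis is None:
                raise ValueError(f"no frozen spline basis for {var!r}")
            block = rcs_transform(basis, pd.to_numeric(df[var]).to_numpy())
            bn = [var] + [f"{term.label()}[{j}]" for j in range(1, block.shape[1])]
        else:  # interaction: all pairwise products of component encodings
            parts = [_encode(df, schema_map[v]) for v in term.variables]
            block, bn = parts[0]
            for nxt, nxt_names in parts[1:]:
                cols, cn = [], []
                for i, j in itertools.product(
                    range(block.shape[1]), range(nxt.shape[1])
                ):
                    cols.append(block[:, i] * nxt[:, j])
                    cn.append(f"{bn[i]}:{nxt_names[j]}")
                block, bn = np.column_stack(cols), cn
        blocks.append(block)
        names.extend(bn)
    X = np.column_stack(blocks)
    complete = ~np.isnan(X).any(axis=1)
    return X, names, complete


def freeze_spline_bases(
    table: SurveyTable,
    models: dict[str, ImputationModel] | list[ImputationModel] | list[TermSpec],
) -> dict[str, RCSBasis]:
    """Compute knot locations once, from genuinely observed records only.

    Pseudo-wave years must not influence knot placement: the spline has to
    be in its linear tail at projection years, which requires knots frozen
    from the *observed* waves.
    """
    if isinstance(models, dict):
        terms = [t for m in models.values() for t in m.terms]
    elif models and isinstance(models[0], ImputationModel):
        terms = [t for m in models for t in m.terms]
    else:
        terms = list(models)  # type: ignore[assignment]
    obs = table.df[table.df[PROVENANCE] == OBSERVED]
    bases: dict[str, RCSBasis] = {}
    for t in terms:
        if t.kind != "spline":
            continue
        var = t.variables[0]
        if var not in bases:
            values = pd.to_numeric(obs[var]).dropna().to_numpy()
            bases[var] = rcs_basis(values, t.spline_df)
    return bases


# ---------------------------------------------------------------------------
# binary logistic regression (ridge-stabilized IRLS)


@dataclass
class FittedModel:
    """A fitted conditional model: estimates, covariance and fit metadata."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_fit: int
    k_par: int
    names: list[str] = field(default_factory=list)


def fit_binary_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-5,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> FittedModel:
    """Ridge-penalized logistic MLE by IRLS with step halving.

    The penalty ``ridge * ||beta||^2`` excludes the intercept (column 0) and
    is applied on internally standardized predictors, which both stabilizes
    the optimization and makes the fit invariant to affine rescaling of a
    predictor.  The returned covariance is the inverse penalized observed
    information, mapped back to the original predictor scale; ``loglik`` is
    the *unpenalized* log-likelihood at the estimate (the quantity BIC
    needs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("design/outcome shape mismatch")
    n, p = X.shape
    if n == 0:
        raise ValueError("empty fitting set")
    levels = np.unique(y)
    if levels.size < 2:
        raise DegenerateOutcomeError(
            f"outcome has a single level {levels!r} among fitting records"
        )
    if not np.isin(levels, (0.0, 1.0)).all():
        raise ValueError("binary outcome must be coded 0/1")

    # standardize non-intercept columns (constant columns left alone)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    pen = np.full(p, float(ridge))
    pen[0] = 0.0

    beta = np.zeros(p)
    eta = Z @ beta
    ll_pen = _bin_loglik(eta, y) - pen @ beta**2
    converged = False
    for _ in range(max_iter):
        prob = expit(eta)
        w = np.clip(prob * (1.0 - prob), 1e-10, None)
        grad = Z.T @ (y - prob) - 2.0 * pen * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = (Z * w[:, None]).T @ Z
        H[np.diag_indices_from(H)] += 2.0 * pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving on the penalized objective
        for _ in range(30):
            cand = beta + step
            eta_c = Z @ cand
            ll_c = _bin_loglik(eta_c, y) - pen @ cand**2
            if ll_c >= ll_pen - 1e-12:
                break
            step *= 0.5
        if abs(ll_c - ll_pen) < tol and np.max(np.abs(step)) < 1e-8:
            beta, eta, ll_pen = cand, eta_c, ll_c
            converged = True
            break
        beta, eta, ll_pen = cand, eta_c, ll_c
    else:
        prob = expit(eta)
        grad = Z.T @ (y - prob) - 2.0 * pen * beta
        converged = np.max(np.abs(grad)) < 1e-4
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(max |grad| = {np.max(np.abs(grad)):.3g}, n = {n}, p = {p})"
        )

    prob = expit(eta)
    w = np.clip(prob * (1.0 - prob), 1e-10, None)
    H = (Z * w[:, None]).T @ Z
    H[np.diag_indices_from(H)] += 2.0 * pen
    cov_z = np.linalg.inv(H)

    # map back to the original scale: beta_x = A @ beta_z
    A = np.zeros((p, p))
    A[0, 0] = 1.0
    for j in range(1, p):
        A[j, j] = 1.0 / sd[j]
        A[0, j] = -mu[j] / sd[j]
    beta_x = A @ beta
    cov_x = A @ cov_z @ A.T

    loglik = _bin_loglik(X @ beta_x, y)
    return FittedModel(
        beta=beta_x,
        cov=cov_x,
        loglik=float(loglik),
        n_fit=n,
        k_par=p,
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
    )


def _bin_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def draw_binary_imputation(
    fit: FittedModel, design_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Proper imputation draw for a binary variable.

    Draws beta* ~ MVN(beta_hat, V_hat) via an eigendecomposition of the
    (symmetrized) covariance, then independent Bernoulli(p*) values with
    p* = logistic(X_mis beta*).
    """
    V = np.asarray(fit.cov, dtype=float)
    V = 0.5 * (V + V.T)
    vals, vecs = np.linalg.eigh(V)
    if vals.min() < -1e-10:
        raise ValueError(
            f"covariance not positive semi-definite (min eigenvalue {vals.min():.3g})"
        )
    vals = np.clip(vals, 0.0, None)
    z = rng.standard_normal(len(fit.beta))
    beta_star = fit.beta + vecs @ (np.sqrt(vals) * z)
    prob = expit(np.asarray(design_mis, dtype=float) @ beta_star)
    return (rng.random(prob.shape[0]) < prob).astype(float)


# ---------------------------------------------------------------------------
# polytomous logistic regression (bootstrap refit)


class _MultinomialFit:
    """Multinomial model fitted on internally standardized predictors."""

    def __init__(self, clf: LogisticRegression, mu: np.ndarray, sd: np.ndarray):
        self._clf = clf
        self._mu = mu
        self._sd = sd

    @property
    def classes_(self) -> np.ndarray:
        return self._clf.classes_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self._mu) / self._sd
        return self._clf.predict_proba(Z)


def fit_multinomial(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-5
) -> tuple[_MultinomialFit, float, int]:
    """Multinomial logistic fit; returns (model, loglik, k_par).

    ``X`` carries its own intercept column, so the solver fits without an
    extra one.  Non-constant columns are centered and scaled internally
    (the optimum is reparametrization-invariant, and lbfgs needs the
    conditioning); a very weak L2 penalty keeps near-separated fits finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateOutcomeError("outcome has a single level")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    mu[constant] = 0.0
    sd[constant] = 1.0
    Z = (X - mu) / sd
    C = 1.0 / max(2.0 * ridge, 1e-12)
    clf = LogisticRegression(
        C=C, fit_intercept=False, solver="lbfgs", max_iter=2000
    )
    clf.fit(Z, y)
    model = _MultinomialFit(clf, mu, sd)
    proba = model.predict_proba(X)
    idx = np.searchsorted(clf.classes_, y)
    loglik = float(np.log(np.clip(proba[np.arange(len(y)), idx], 1e-300, None)).sum())
    k_par = (classes.size - 1) * X.shape[1]
    return model, loglik, k_par


def draw_polytomous_imputation(
    design_obs: np.ndarray,
    y_obs: np.ndarray,
    design_mis: np.ndarray,
    rng: np.random.Generator,
    ridge: float = 1e-5,
    max_retry: int = 10,
) -> np.ndarray:
    """Bootstrap-refit imputation draw for a categorical variable.

    Resamples the fitting records with replacement (retrying, at most
    ``max_retry`` times, until every observed level is present), refits the
    multinomial model on the resample, and draws each missing value from the
    fitted category probabilities.
    """
    y_obs = np.asarray(y_obs)
    levels = np.unique(y_obs)
    if levels.size < 2:
        raise DegenerateOutcomeError("outcome has a single level")
    n = len(y_obs)
    for _ in range(max_retry):
        idx = rng.integers(0, n, n)
        if np.unique(y_obs[idx]).size == levels.size:
            break
    else:
        raise RuntimeError(
            f"could not draw a bootstrap resample containing all "
            f"{levels.size} levels in {max_retry} tries"
        )
    clf, _, _ = fit_multinomial(design_obs[idx], y_obs[idx], ridge)
    proba = clf.predict_proba(np.asarray(design_mis, dtype=float))
    cum = np.cumsum(proba, axis=1)
    u = rng.random(proba.shape[0])
    choice = (u[:, None] > cum).sum(axis=1)
    return clf.classes_[choice]


# ---------------------------------------------------------------------------
# BIC and forward stepwise selection


def bic(fit: FittedModel) -> float:
    """Bayesian information criterion, k ln(n) - 2 log L (lower is better)."""
    if fit.n_fit <= 0:
        raise ValueError("BIC undefined for an empty fit")
    return fit.k_par * math.log(fit.n_fit) - 2.0 * fit.loglik


def _fit_terms(
    df: pd.DataFrame,
    outcome: str,
    terms: list[TermSpec],
    schema_map: dict[str, VariableSpec],
    spline_bases: dict[str, RCSBasis],
    family: str,
    ridge: float,
) -> FittedModel:
    X, names, complete = build_design(df, terms, schema_map, spline_bases)
    if not complete.all():
        raise ValueError("selection fitting set must be complete")
    spec = schema_map[outcome]
    if family == "binary-logistic":
        y = pd.to_numeric(df[outcome]).to_numpy(dtype=float)
        return fit_binary_logistic(X, y, ridge=ridge, names=names)
    y = df[outcome].to_numpy()
    _, loglik, k_par = fit_multinomial(X, y, ridge)
    return FittedModel(
        beta=np.zeros(0), cov=np.zeros((0, 0)), loglik=loglik,
        n_fit=len(df), k_par=k_par, names=names,
    )


def _effective_terms(current: list[TermSpec], cand: TermSpec) -> list[TermSpec]:
    """Add a candidate; a spline replaces the main effect of its variable
    (and vice versa), so linear-vs-spline enter the search as competitors."""
    terms = list(current)
    if cand.kind == "spline":
        terms = [
            t for t in terms
            if not (t.kind == "main" and t.variables == cand.variables)
        ]
    elif cand.kind == "main":
        terms = [
            t for t in terms
            if not (t.kind == "spline" and t.variables == cand.variables)
        ]
    return terms + [cand]


def select_model(
    table: SurveyTable,
    outcome: str,
    base_terms: list[TermSpec],
    candidate_terms: list[TermSpec],
    ridge: float = 1e-5,
) -> ImputationModel:
    """Forward stepwise BIC search over candidate predictor terms.

    Starting from ``base_terms``, repeatedly adds the candidate that lowers
    BIC the most, stopping when no candidate lowers it.  The fitting set is
    available-case: genuinely observed records with the outcome and every
    candidate predictor present (selection happens before imputation, so
    complete-predictor records are all that can be used).
    """
    schema_map = table.schema_map
    if outcome not in schema_map:
        raise ValueError(f"unknown outcome {outcome!r}")
    family = (
        "binary-logistic"
        if schema_map[outcome].vtype == "binary"
        else "polytomous-logistic"
    )
    all_terms = list(base_terms) + list(candidate_terms)
    spline_bases = freeze_spline_bases(table, all_terms)
    used_vars = {v for t in all_terms for v in t.variables} | {outcome}

    df = table.df
    mask = (df[PROVENANCE] == OBSERVED) & df[outcome].notna()
    for v in used_vars:
        mask &= df[v].notna()
    fit_df = df[mask]
    if fit_df.empty:
        raise ValueError("empty fitting set for model selection")

    current = list(base_terms)
    current_bic = bic(
        _fit_terms(fit_df, outcome, current, schema_map, spline_bases, family, ridge)
    )
    remaining = list(candidate_terms)
    while remaining:
        scores = []
        for cand in remaining:
            trial = _effective_terms(current, cand)
            try:
                b = bic(
                    _fit_terms(
                        fit_df, outcome, trial, schema_map, spline_bases,
                        family, ridge,
                    )
                )
            except (DegenerateOutcomeError, ConvergenceError, ValueError):
                b = math.inf
            scores.append(b)
        best = int(np.argmin(scores))
        if scores[best] >= current_bic:
            break
        current = _effective_terms(current, remaining[best])
        current_bic = scores[best]
        remaining.pop(best)
    return ImputationModel(outcome, tuple(current), family, ridge)


__all__ = [
    "TermSpec",
    "main",
    "interaction",
    "spline",
    "ImputationModel",
    "FittedModel",
    "DegenerateOutcomeError",
    "ConvergenceError",
    "build_design",
    "freeze_spline_bases",
    "fit_binary_logistic",
    "draw_binary_imputation",
    "fit_multinomial",
    "draw_polytomous_imputation",
    "bic",
    "select_model",
]
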