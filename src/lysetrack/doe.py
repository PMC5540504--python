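"""Full-factorial design generation and screening-model evaluation.

The homogenization screening study varies pressure (bar), biomass
(g DCW/L) and number of passes over a full factorial grid and models the
biomass-normalized total peak area with an ordinary-least-squares model on
coded factors (each factor mapped affinely so its lowest level is -1 and
its highest +1): intercept, linear main effects and, by default, all
two-factor interactions — the standard screening term set.

Model quality is summarized by the goodness of fit R^2 = 1 - SSE/SStot
and the goodness of prediction Q^2 = 1 - PRESS/SStot, with PRESS from
closed-form leave-one-out residuals e_i / (1 - h_i) (h_i the leverage).
Since |1 - h_i| <= 1, PRESS >= SSE and Q^2 <= R^2 for every fit.
Per-coefficient two-sided p-values come from the t distribution on the
residual degrees of freedom.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "FactorSpec",
    "DoEDesign",
    "ContourGrid",
    "full_factorial",
    "code_factors",
    "FactorialScreeningModel",
    "fit_screening_model",
    "predict_surface",
    "homogenization_screening_factors",
]


@dataclass(frozen=True)
class FactorSpec:
    """One numeric factor of the design: name, sorted levels, role."""

    name: str
    levels: tuple[float, ...]
    role: str = "quantitative"

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.levels)
        if len(set(levels)) < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 distinct levels")
        object.__setattr__(self, "levels", tuple(sorted(set(levels))))
        if self.role not in ("quantitative", "quantitative-multilevel"):
            raise ValueError(f"unknown factor role {self.role!r}")

    @property
    def lo(self) -> float:
        return self.levels[0]

    @property
    def hi(self) -> float:
        return self.levels[-1]

    def code(self, x):
        """Affine map of natural units onto [-1, +1]."""
        x = np.asarray(x, dtype=float)
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def decode(self, z):
        z = np.asarray(z, dtype=float)
        return self.lo + (z + 1.0) * (self.hi - self.lo) / 2.0


@dataclass
class DoEDesign:
    """Run table (run_id + one column per factor) with its factor specs."""

    runs: pd.DataFrame
    factors: list[FactorSpec] = field(default_factory=list)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]


def homogenization_screening_factors() -> list[FactorSpec]:
    """The disruption screening space: pressure x biomass x cycles.

    Pressure 500/1000/1500 bar and biomass 10/55/100 g DCW/L as three-level
    quantitative factors, homogenization cycles 0-3 as a quantitative
    multilevel factor — a 3 x 3 x 4 = 36-run full factorial.
    """
    return [
        FactorSpec("pressure_bar", (500.0, 1000.0, 1500.0)),
        FactorSpec("biomass_gdcw_per_l", (10.0, 55.0, 100.0)),
        FactorSpec("cycles", (0.0, 1.0, 2.0, 3.0), role="quantitative-multilevel"),
    ]


def full_factorial(factors: list[FactorSpec]) -> DoEDesign:
    """All level combinations, ordered lexicographically by factor then level."""
    if not factors:
        raise ValueError("factor list must not be empty")
    combos = list(itertools.product(*(f.levels for f in factors)))
    runs = pd.DataFrame(combos, columns=[f.name for f in factors])
    runs.insert(0, "run_id", np.arange(1, len(runs) + 1))
    return DoEDesign(runs=runs, factors=list(factors))


def code_factors(design: DoEDesign) -> pd.DataFrame:
    """Coded run table: every factor mapped so min -> -1 and max -> +1."""
    coded = {}
    for f in design.factors:
        coded[f.name] = f.code(design.runs[f.name].to_numpy())
    return pd.DataFrame(coded, index=design.runs.index)


def _term_matrix(Z: np.ndarray, names: list[str], interactions: bool):
    cols = [np.ones(Z.shape[0])]
    term_names = ["intercept"]
    for j, name in enumerate(names):
        cols.append(Z[:, j])
        term_names.append(name)
    if interactions:
        for j, k in itertools.combinations(range(len(names)), 2):
            cols.append(Z[:, j] * Z[:, k])
            term_names.append(f"{names[j]}:{names[k]}")
    return np.column_stack(cols), term_names


def _aliased_terms(T: np.ndarray, names: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(T)
    _, _, piv = qr(T, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


class FactorialScreeningModel(RegressorMixin, BaseEstimator):
    """OLS screening model on coded factors, scikit-learn style.

    ``fit(X, y)`` takes the factor settings in natural units (columns in
    the order of ``factors``) and the response; internally the factors are
    coded to [-1, +1] and the term matrix (intercept, main effects,
    optional two-factor interactions) is fitted by ordinary least squares.

    Parameters
    ----------
    factors : list of FactorSpec, optional
        Coding ranges and names. If omitted, ranges are inferred from the
        column minima/maxima at fit time and factors are named x1..xk.
    interactions : bool, default True
        Include all two-factor interaction terms.

    Attributes
    ----------
    coef_ : ndarray, non-intercept coefficients on coded factors.
    intercept_ : float
    term_names_ : list of str, ``["intercept", ...]`` matching ``params_``.
    params_ : ndarray, all coefficients including the intercept.
    p_values_ : ndarray, two-sided t-test p-value per term.
    r2_, q2_ : goodness of fit and leave-one-out goodness of prediction.
    press_, leverage_ : PRESS statistic and per-run hat values.
    """

    def __init__(self, factors: list[FactorSpec] | None = None, interactions: bool = True):
        self.factors = factors
        self.interactions = interactions

    def _resolve_factors(self, X: np.ndarray) -> list[FactorSpec]:
        if self.factors is not None:
            if len(self.factors) != X.shape[1]:
                raise ValueError(
                    f"X has {X.shape[1]} columns but {len(self.factors)} factors declared"
                )
            return list(self.factors)
        specs = []
        for j in range(X.shape[1]):
            lo, hi = X[:, j].min(), X[:, j].max()
            if lo == hi:
                raise ValueError(f"factor x{j + 1} is constant; cannot code it")
            specs.append(FactorSpec(f"x{j + 1}", (lo, hi)))
        return specs

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.factors_ = self._resolve_factors(X)
        Z = np.column_stack([f.code(X[:, j]) for j, f in enumerate(self.factors_)])
        T, names = _term_matrix(Z, [f.name for f in self.factors_], self.interactions)
        if X.shape[0] < T.shape[1]:
            raise ValueError(
                f"{X.shape[0]} runs cannot identify {T.shape[1]} model terms"
            )
        if np.linalg.matrix_rank(T) < T.shape[1]:
            aliased = _aliased_terms(T, names)
            raise ValueError(
                "design is rank-deficient; aliased terms: " + ", ".join(aliased)
            )
        res = sm.OLS(y, T).fit()
        h = res.get_influence().hat_matrix_diag
        resid = res.resid
        sse = float(resid @ resid)
        sstot = float(np.sum((y - y.mean()) ** 2))
        loo = resid / np.where(1.0 - h > 1e-12, 1.0 - h, np.nan)
        press = float(np.nansum(loo**2))
        if np.any(1.0 - h <= 1e-12):
            warnings.warn(
                "saturated runs (leverage 1); their LOO residuals are undefined",
                RuntimeWarning,
                stacklevel=2,
            )
        self.term_names_ = names
        self.params_ = np.asarray(res.params, dtype=float)
        self.intercept_ = float(self.params_[0])
        self.coef_ = self.params_[1:].copy()
        self.p_values_ = np.asarray(res.pvalues, dtype=float)
        self.r2_ = 1.0 - (sse / sstot if sstot > 0 else 0.0)
        self.q2_ = 1.0 - (press / sstot if sstot > 0 else 0.0)
        self.press_ = press
        self.leverage_ = h
        self.n_features_in_ = X.shape[1]
        self._ols_result = res
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        Z = np.column_stack([f.code(X[:, j]) for j, f in enumerate(self.factors_)])
        T, _ = _term_matrix(Z, [f.name for f in self.factors_], self.interactions)
        return T @ self.params_

    def p_value(self, term: str) -> float:
        """p-value of one named term (e.g. ``"pressure_bar"``)."""
        check_is_fitted(self, "params_")
        try:
            return float(self.p_values_[self.term_names_.index(term)])
        except ValueError:
            raise KeyError(f"unknown model term {term!r}") from None

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: term, coefficient, p_value."""
        check_is_fitted(self, "params_")
        return pd.DataFrame(
            {"term": self.term_names_, "coefficient": self.params_, "p_value": self.p_values_}
        )


def fit_screening_model(
    design: DoEDesign | pd.DataFrame,
    response,
    factors: list[FactorSpec] | None = None,
    interactions: bool = True,
) -> FactorialScreeningModel:
    """Fit the screening model to a run table and response vector."""
    if isinstance(design, DoEDesign):
        factors = factors or design.factors
        X = design.runs[[f.name for f in factors]].to_numpy(dtype=float)
    else:
        if factors is None:
            raise ValueError("factors are required when passing a bare run table")
        X = design[[f.name for f in factors]].to_numpy(dtype=float)
    model = FactorialScreeningModel(factors=factors, interactions=interactions)
    return model.fit(X, np.asarray(response, dtype=float))


@dataclass
class ContourGrid:
    """Predicted response over a 2-D slice of the design space."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    fixed: dict[str, float]
    predicted: np.ndarray  # shape (len(axis2_values), len(axis1_values))

    def to_frame(self) -> pd.DataFrame:
        """Matrix with axis-1 levels as columns and axis-2 levels as rows."""
        return pd.DataFrame(
            self.predicted,
            index=pd.Index(self.axis2_values, name=self.axis2_name),
            columns=pd.Index(self.axis1_values, name=self.axis1_name),
        )


def predict_surface(
    model: FactorialScreeningModel,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    fixed: dict[str, float] | None = None,
) -> ContourGrid:
    """Evaluate the fitted model on a 2-D grid, remaining factors fixed.

    Grid points outside a factor's design range trigger an extrapolation
    warning but are still evaluated.
    """
    check_is_fitted(model, "params_")
    fixed = dict(fixed or {})
    names = [f.name for f in model.factors_]
    a1_name, a1_vals = axis1[0], np.asarray(axis1[1], dtype=float)
    a2_name, a2_vals = axis2[0], np.asarray(axis2[1], dtype=float)
    for name in (a1_name, a2_name, *fixed):
        if name not in names:
            raise KeyError(f"unknown factor {name!r}; model factors: {names}")
    missing = set(names) - {a1_name, a2_name} - set(fixed)
    if missing:
        raise ValueError(f"no value fixed for factors: {sorted(missing)}")
    for f in model.factors_:
        vals = {a1_name: a1_vals, a2_name: a2_vals}.get(f.name)
        vals = vals if vals is not None else np.array([fixed[f.name]])
        if vals.min() < f.lo - 1e-9 or vals.max() > f.hi + 1e-9:
            warnings.warn(
                f"grid extrapolates beyond the design range of {f.name!r}",
                UserWarning,
                stacklevel=2,
            )
    g1, g2 = np.meshgrid(a1_vals, a2_vals)
    X = np.empty((g1.size, len(names)))
    for j, name in enumerate(names):
        if name == a1_name:
            X[:, j] = g1.ravel()
        elif name == a2_name:
            X[:, j] = g2.ravel()
        else:
            X[:, j] = fixed[name]
    pred = model.predict(X).reshape(g1.shape)
    return ContourGrid(
        axis1_name=a1_name,
        axis1_values=a1_vals,
        axis2_name=a2_name,
        axis2_values=a2_vals,
        fixed={k: v for k, v in fixed.items()},
        predicted=pred,
    )
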