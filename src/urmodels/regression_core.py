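"""OLS fitting with classical reported standard errors.

All regressions in the package — the standard series of outcome models,
the UR preparation regressions, and the composite UR model — pass
through :func:`fit_ols`, a thin surface over :mod:`statsmodels` OLS with
an always-included intercept and the homoskedastic (model summary
output) standard errors with denominator ``n - p - 1``.

Collinearity is a hard error here, never silent column dropping: the UR
construction relies on the exact orthogonality of residuals to the
covariates of their preparation fits, which silent dropping would break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scenario_dag import PlanRole, RegressionPlan, ScenarioSpec
from .sem_sim import Dataset

__all__ = [
    "FitResult",
    "StandardSeries",
    "CollinearityError",
    "fit_ols",
    "standard_series",
    "as_frame",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the dependent columns."""


@dataclass
class FitResult:
    """Coefficients, reported SEs and residual diagnostics of one OLS fit."""

    response: str
    intercept: float
    coefficients: dict[str, float]
    reported_se: dict[str, float]
    intercept_se: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    p: int
    plan: RegressionPlan | None = None

    def predict(self, data: pd.DataFrame | Mapping[str, np.ndarray]) -> np.ndarray:
        """Linear predictor on new columns (same covariate names)."""
        out = np.full(len(next(iter(data.values())) if isinstance(data, dict) else data), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * np.asarray(data[name], dtype=float)
        return out

    def tidy(self, model_id: str = "") -> pd.DataFrame:
        """Fit summary as a tidy table (term, estimate, reported_se)."""
        terms = ["(intercept)"] + list(self.coefficients)
        est = [self.intercept] + list(self.coefficients.values())
        se = [self.intercept_se] + [self.reported_se[t] for t in self.coefficients]
        return pd.DataFrame(
            {"term": terms, "estimate": est, "reported_se": se, "model_id": model_id}
        )


@dataclass
class StandardSeries:
    """The k standard regression models and their total-effect estimates.

    ``total_effects`` keeps, from model ``i``, only the coefficient of
    the most recent exposure measurement ``x_i`` — the only coefficient
    in that model interpretable as a total causal effect.
    """

    fits: list[FitResult]
    total_effects: dict[str, float]


def as_frame(data: Dataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, Dataset):
        return data.df
    return data


def _dependent_columns(X: np.ndarray, names: list[str], rank: int) -> list[str]:
    """Columns involved in a linear dependency (removal keeps the rank)."""
    bad = []
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(name)
    return bad


def fit_ols(data: Dataset | pd.DataFrame, plan: RegressionPlan) -> FitResult:
    """Ordinary least squares of ``plan.response`` on ``plan.covariates``.

    Always includes an intercept; reported SEs are the classical
    homoskedastic estimates (residual variance with denominator
    ``n - p - 1``).
    """
    df = as_frame(data)
    missing = [c for c in (plan.response, *plan.covariates) if c not in df.columns]
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    y = df[plan.response].to_numpy(dtype=float)
    names = list(plan.covariates)
    X = df[names].to_numpy(dtype=float) if names else np.empty((len(y), 0))
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        bad = _dependent_columns(design[:, 1:], names, np.linalg.matrix_rank(design[:, 1:]) )
        raise CollinearityError(
            f"design for {plan.response} is rank deficient; "
            f"linearly dependent columns: {bad or names}"
        )
    res = sm.OLS(y, design).fit()
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    return FitResult(
        response=plan.response,
        intercept=float(params[0]),
        coefficients={name: float(params[j + 1]) for j, name in enumerate(names)},
        reported_se={name: float(bse[j + 1]) for j, name in enumerate(names)},
        intercept_se=float(bse[0]),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        n=n,
        p=p,
        plan=plan,
    )


def standard_series(data: Dataset | pd.DataFrame, spec: ScenarioSpec) -> StandardSeries:
    """Fit the k standard regression models for a scenario.

    Thin wrapper over :class:`urmodels.estimators.StandardSeriesRegressor`.
    """
    from .estimators import StandardSeriesRegressor

    est = StandardSeriesRegressor(
        scenario=spec.kind.value,
        k=spec.k,
        exposure_name=spec.exposure_name,
        outcome_name=spec.outcome_name,
        confounder_name=spec.confounder_name,
    )
    est.fit(as_frame(data))
    return StandardSeries(fits=est.fits_, total_effects=dict(est.total_effects_))
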