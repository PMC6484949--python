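"""Scikit-learn style estimators for the standard and UR regressions.

Two regressors share a scenario-aware base:

:class:`StandardSeriesRegressor`
    fits the ``k`` standard outcome models (one per exposure time
    point, each adjusted for everything temporally preceding its most
    recent exposure measurement) and collects the total-effect
    estimates;
:class:`URRegressor`
    runs the two-stage unexplained-residuals procedure — preparation
    regressions whose residuals become orthogonal UR covariates, then
    the single composite model of the outcome on the initial
    measurement(s) and all UR terms — with optional deliberate
    misadjustment of the confounder for bias experiments.

Both accept a named-column :class:`pandas.DataFrame` (the outcome may
be a column of ``X`` or passed separately as ``y``) and follow sklearn
conventions: parameters set in ``__init__``, fitted attributes with a
trailing underscore, ``get_params``/``set_params``/``clone`` support.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .regression_core import FitResult, fit_ols
from .scenario_dag import (
    AdjustmentMode,
    PlanRole,
    RegressionPlan,
    ScenarioSpec,
    regression_plans,
    ur_plans,
)
from .sem_sim import Dataset

__all__ = ["StandardSeriesRegressor", "URRegressor"]


class _ScenarioRegressor(RegressorMixin, BaseEstimator):
    """Shared scenario handling and input validation."""

    def __init__(
        self,
        scenario: str = "no_confounder",
        k: int = 2,
        exposure_name: str = "x",
        outcome_name: str = "y",
        confounder_name: str = "m",
    ):
        self.scenario = scenario
        self.k = k
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.confounder_name = confounder_name

    def _make_spec(self) -> ScenarioSpec:
        return ScenarioSpec(
            kind=self.scenario,
            k=self.k,
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            confounder_name=self.confounder_name,
        )

    def _predictor_columns(self, spec: ScenarioSpec) -> list[str]:
        return [c for c in spec.nodes if c != spec.outcome_name]

    def _to_frame(self, X, y, spec: ScenarioSpec, require_outcome: bool) -> pd.DataFrame:
        """Named frame with all scenario columns (outcome included if needed)."""
        if isinstance(X, Dataset):
            X = X.df
        predictors = self._predictor_columns(spec)
        if isinstance(X, pd.DataFrame):
            df = X.copy()
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(predictors):
                raise ValueError(
                    f"array input must have {len(predictors)} columns "
                    f"(temporal order {predictors}); got shape {arr.shape}"
                )
            df = pd.DataFrame(arr, columns=predictors)
        if y is not None:
            df = df.assign(**{spec.outcome_name: np.asarray(y, dtype=float)})
        needed = predictors + ([spec.outcome_name] if require_outcome else [])
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        if df[needed].isna().any().any():
            raise ValueError("input contains missing values")
        return df

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"X_types": ["2darray", "dataframe"], "allow_nan": False}


class StandardSeriesRegressor(_ScenarioRegressor):
    """The series of k standard regression models of a distal outcome.

    Model ``i`` regresses the outcome on all confounder and exposure
    measurements up to time ``i``; only the coefficient of the most
    recent exposure ``x_i`` is interpretable as a total causal effect,
    and these are collected in ``total_effects_``.

    Attributes
    ----------
    fits_ : list of FitResult
        The k fitted models in time order.
    total_effects_ : dict
        ``x_i -> coefficient of x_i in model i``.
    coef_, intercept_ : final (model k) coefficients, sklearn style.
    """

    def fit(self, X, y=None):
        spec = self._make_spec()
        df = self._to_frame(X, y, spec, require_outcome=True)
        plans = [
            p
            for p in regression_plans(spec)
            if p.role is PlanRole.STANDARD_SERIES
        ]
        self.spec_ = spec
        self.fits_ = [fit_ols(df, p) for p in plans]
        self.total_effects_ = {
            spec.exposure(i): fit.coefficients[spec.exposure(i)]
            for i, fit in enumerate(self.fits_, start=1)
        }
        final = self.fits_[-1]
        self.covariate_names_ = list(final.coefficients)
        self.coef_ = np.array(list(final.coefficients.values()))
        self.intercept_ = final.intercept
        self.n_features_in_ = len(self._predictor_columns(spec))
        return self

    def predict(self, X):
        check_is_fitted(self, "fits_")
        df = self._to_frame(X, None, self.spec_, require_outcome=False)
        return self.fits_[-1].predict(df)


class URRegressor(_ScenarioRegressor):
    """Two-stage unexplained-residuals (conditional) regression.

    Stage one fits, in temporal order, the preparation regressions of
    each post-baseline measurement on everything that precedes it
    (including the confounder, unless a misadjustment mode omits it)
    and stores the residuals as UR columns ``e_x2..e_xk`` (and
    ``e_m2..e_mk`` for a time-varying confounder).  Stage two fits the
    composite model of the outcome on the baseline measurement(s) and
    the UR terms.

    Parameters
    ----------
    adjustment_mode : str
        ``"correct"`` or one of the deliberate misadjustments
        ``"omit_confounder_in_prep"``, ``"omit_confounder_in_composite"``,
        ``"omit_both"`` (confounded scenarios only).

    Attributes
    ----------
    prep_fits_ : list of FitResult
        Preparation regressions, in fit order.
    ur_ : pandas.DataFrame
        The generated UR columns (sample mean 0 by construction).
    composite_fit_ : FitResult
        The composite UR model.
    coef_, intercept_, se_ : composite coefficients, intercept and
        classical reported SEs.
    """

    def __init__(
        self,
        scenario: str = "no_confounder",
        k: int = 2,
        adjustment_mode: str = "correct",
        exposure_name: str = "x",
        outcome_name: str = "y",
        confounder_name: str = "m",
    ):
        super().__init__(
            scenario=scenario,
            k=k,
            exposure_name=exposure_name,
            outcome_name=outcome_name,
            confounder_name=confounder_name,
        )
        self.adjustment_mode = adjustment_mode

    # -- stage one ----------------------------------------------------
    @staticmethod
    def _build_ur(
        df: pd.DataFrame, prep_plans: list[RegressionPlan], spec: ScenarioSpec
    ) -> tuple[pd.DataFrame, list[FitResult]]:
        """Fit preparation regressions and collect residual columns."""
        ur = {}
        fits = []
        for plan in prep_plans:
            fit = fit_ols(df, plan)
            fits.append(fit)
            ur[spec.ur_name(plan.response)] = fit.residuals
        return pd.DataFrame(ur, index=df.index), fits

    def fit(self, X, y=None):
        spec = self._make_spec()
        mode = AdjustmentMode(self.adjustment_mode)
        df = self._to_frame(X, y, spec, require_outcome=True)
        prep_plans, composite_plan = ur_plans(spec, mode)
        ur, prep_fits = self._build_ur(df, prep_plans, spec)
        work = pd.concat([df, ur], axis=1)

        self.spec_ = spec
        self.mode_ = mode
        self.prep_fits_ = prep_fits
        self.ur_ = ur
        self.composite_plan_ = composite_plan
        self.composite_fit_ = fit_ols(work, composite_plan)
        self.design_ = work[list(composite_plan.covariates)]
        self.covariate_names_ = list(composite_plan.covariates)
        self.coef_ = np.array(
            [self.composite_fit_.coefficients[c] for c in self.covariate_names_]
        )
        self.intercept_ = self.composite_fit_.intercept
        self.se_ = dict(self.composite_fit_.reported_se)
        self.n_features_in_ = len(self._predictor_columns(spec))
        return self

    def _ur_for(self, df: pd.DataFrame) -> pd.DataFrame:
        """UR columns for new data from the stored preparation fits."""
        ur = {}
        work = df.copy()
        for fit in self.prep_fits_:
            resid = work[fit.response].to_numpy(dtype=float) - fit.predict(work)
            name = self.spec_.ur_name(fit.response)
            ur[name] = resid
            work[name] = resid
        return pd.DataFrame(ur, index=df.index)

    def predict(self, X):
        check_is_fitted(self, "composite_fit_")
        df = self._to_frame(X, None, self.spec_, require_outcome=False)
        work = pd.concat([df, self._ur_for(df)], axis=1)
        return self.composite_fit_.predict(work)
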