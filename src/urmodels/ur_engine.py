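"""UR-term generation, the composite UR model, and its exact properties.

The functions here are thin wrappers over
:class:`urmodels.estimators.URRegressor`; they expose the procedure in
its two classical stages and verify the three algebraic properties that
a correctly adjusted UR analysis guarantees:

(i)   the composite UR model reproduces the fitted values of the final
      standard regression model;
(ii)  the composite coefficient of ``x1`` equals the ``x1`` coefficient
      of the first standard model;
(iii) the composite coefficient of each UR term ``e_xi`` equals the
      ``x_i`` coefficient of standard model ``i``.

These are exact in exact arithmetic, so the default tolerance only has
to absorb floating error.  The module also computes the *population*
composite coefficients from the implied covariance of a generating DAG,
which yields the exact asymptotic omitted-variable bias of the
misadjusted variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression_core import FitResult, StandardSeries, as_frame, standard_series
from .scenario_dag import (
    AdjustmentMode,
    PathDAG,
    PlanRole,
    ScenarioSpec,
    ur_plans,
)
from .sem_sim import Dataset, implied_covariance

__all__ = [
    "URDecomposition",
    "CompositeURFit",
    "PropertyReport",
    "make_ur_terms",
    "fit_composite_ur",
    "check_properties",
    "population_ur_coefficients",
]

#: Properties (i)-(iii) are exact identities of OLS algebra; only
#: floating error remains, so equality is checked at 1e-10.
DEFAULT_TOLERANCE = 1e-10


@dataclass
class URDecomposition:
    """Generated UR columns plus the preparation fits that made them."""

    ur_columns: pd.DataFrame
    prep_fits: list[FitResult]
    adjustment_mode: AdjustmentMode
    spec: ScenarioSpec


@dataclass
class PropertyReport:
    """Discrepancies between a composite UR fit and the standard series."""

    prop_i_max_abs_diff: float
    prop_ii_abs_diff: float
    prop_iii_abs_diffs: dict[str, float]
    max_abs_offdiag_corr: float
    passed: bool
    tolerance: float = DEFAULT_TOLERANCE


@dataclass
class CompositeURFit:
    """The composite UR model and its comparison against the standard series."""

    fit: FitResult
    design: pd.DataFrame
    property_report: "PropertyReport | None"
    adjustment_mode: AdjustmentMode


def make_ur_terms(
    data: Dataset | pd.DataFrame,
    spec: ScenarioSpec,
    mode: AdjustmentMode | str = AdjustmentMode.CORRECT,
) -> URDecomposition:
    """Stage one: fit the preparation regressions and keep their residuals.

    For ``i = 2..k`` each exposure measurement is regressed on all
    temporally preceding variables (misadjustment modes drop the
    confounder from this stage); a time-varying confounder is
    residualised the same way, ``e_m_i`` before ``e_x_i``.
    """
    from .estimators import URRegressor

    mode = AdjustmentMode(mode)
    df = as_frame(data)
    prep_plans, _ = ur_plans(spec, mode)
    ur, prep_fits = URRegressor._build_ur(df, prep_plans, spec)
    return URDecomposition(ur_columns=ur, prep_fits=prep_fits,
                           adjustment_mode=mode, spec=spec)


def fit_composite_ur(
    data: Dataset | pd.DataFrame,
    dec: URDecomposition,
    spec: ScenarioSpec | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> CompositeURFit:
    """Stage two: fit the composite UR model and check its properties.

    The composite model regresses the outcome on the baseline
    measurement(s) and the UR columns of ``dec`` (minus whatever the
    decomposition's misadjustment mode omits), then populates a
    :class:`PropertyReport` against the standard series fitted on the
    same data.
    """
    from .regression_core import fit_ols

    spec = spec or dec.spec
    df = as_frame(data)
    if len(dec.ur_columns) != len(df):
        raise ValueError("UR decomposition was generated from different data")
    _, composite_plan = ur_plans(spec, dec.adjustment_mode)
    work = pd.concat([df, dec.ur_columns], axis=1)
    fit = fit_ols(work, composite_plan)
    design = work[list(composite_plan.covariates)]
    series = standard_series(df, spec)
    composite = CompositeURFit(
        fit=fit,
        design=design,
        property_report=None,  # filled below
        adjustment_mode=dec.adjustment_mode,
    )
    composite.property_report = check_properties(series, composite, tolerance)
    return composite


def _rel_diff_ok(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol * max(1.0, abs(a))


def check_properties(
    series: StandardSeries,
    composite: CompositeURFit,
    tolerance: float = DEFAULT_TOLERANCE,
) -> PropertyReport:
    """Quantify Properties (i)-(iii) and the composite design orthogonality.

    Both inputs must have been fitted on identical data.  For a
    misadjusted composite the discrepancy fields quantify the
    omitted-variable bias instead of vanishing.
    """
    final = series.fits[-1]
    if len(final.fitted) != len(composite.fit.fitted):
        raise ValueError("standard series and composite were fitted on different data")
    spec_cols = list(composite.fit.coefficients)

    prop_i = float(np.max(np.abs(final.fitted - composite.fit.fitted)))

    first = series.fits[0]
    x1 = first.plan.covariates[-1]  # most recent exposure of model 1
    prop_ii = abs(first.coefficients[x1] - composite.fit.coefficients[x1])

    prop_iii: dict[str, float] = {}
    ok_iii = True
    for i, fit in enumerate(series.fits[1:], start=2):
        xi = fit.plan.covariates[-1]
        e_name = f"e_{xi}"
        if e_name not in composite.fit.coefficients:
            continue
        alpha = fit.coefficients[xi]
        lam = composite.fit.coefficients[e_name]
        prop_iii[xi] = abs(alpha - lam)
        ok_iii &= _rel_diff_ok(alpha, lam, tolerance)

    # orthogonality of the composite design, over pairs involving a UR term
    corr = composite.design.corr().to_numpy()
    names = list(composite.design.columns)
    is_ur = np.array([c.startswith("e_") for c in names])
    max_corr = 0.0
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if is_ur[a] or is_ur[b]:
                max_corr = max(max_corr, abs(corr[a, b]))

    alpha1 = first.coefficients[x1]
    passed = (
        prop_i <= tolerance * max(1.0, float(np.max(np.abs(final.fitted))))
        and _rel_diff_ok(alpha1, composite.fit.coefficients[x1], tolerance)
        and ok_iii
    )
    return PropertyReport(
        prop_i_max_abs_diff=prop_i,
        prop_ii_abs_diff=float(prop_ii),
        prop_iii_abs_diffs=prop_iii,
        max_abs_offdiag_corr=float(max_corr),
        passed=bool(passed),
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# population (asymptotic) analysis


def population_ur_coefficients(
    dag: PathDAG,
    spec: ScenarioSpec,
    mode: AdjustmentMode | str = AdjustmentMode.CORRECT,
) -> dict[str, float]:
    """Population coefficients of the composite UR model under a mode.

    Works entirely from the implied covariance of ``dag``: each UR
    column is represented as the population least-squares residual of
    its preparation regression (a linear combination of observed
    nodes), and the composite coefficients solve the population normal
    equations over those combinations.  Under ``correct`` adjustment
    the ``x1`` coefficient equals the true total effect of ``x1`` on
    the outcome; under the ``omit_*`` modes the difference from that
    total effect is the exact asymptotic omitted-variable bias.
    """
    mode = AdjustmentMode(mode)
    sigma = implied_covariance(dag).to_numpy()
    nodes = list(dag.nodes)
    idx = {v: j for j, v in enumerate(nodes)}

    # variables as coefficient vectors over the observed nodes
    vectors: dict[str, np.ndarray] = {}
    for v in nodes:
        e = np.zeros(len(nodes))
        e[idx[v]] = 1.0
        vectors[v] = e

    def cov(u: np.ndarray, w: np.ndarray) -> float:
        return float(u @ sigma @ w)

    prep_plans, composite_plan = ur_plans(spec, mode)
    for plan in prep_plans:
        C = [vectors[c] for c in plan.covariates]
        gram = np.array([[cov(a, b) for b in C] for a in C])
        rhs = np.array([cov(a, vectors[plan.response]) for a in C])
        beta = np.linalg.solve(gram, rhs)
        resid = vectors[plan.response] - sum(b * c for b, c in zip(beta, C))
        vectors[spec.ur_name(plan.response)] = resid

    C = [vectors[c] for c in composite_plan.covariates]
    gram = np.array([[cov(a, b) for b in C] for a in C])
    rhs = np.array([cov(a, vectors[composite_plan.response]) for a in C])
    beta = np.linalg.solve(gram, rhs)
    return {name: float(b) for name, b in zip(composite_plan.covariates, beta)}
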