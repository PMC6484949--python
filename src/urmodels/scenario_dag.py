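"""Canonical lifecourse confounding scenarios and their regression plans.

Three data-generating scenarios are supported, each a forwardly saturated
DAG (every node may causally affect every later node) over ``k``
longitudinal measurements of an exposure ``x`` and one distal outcome
``y``:

``no_confounder``
    nodes ``x1, ..., xk, y``;
``time_invariant``
    adds a single baseline confounder ``m`` preceding all exposures;
``time_varying``
    adds a repeatedly measured confounder ``m1, ..., mk`` with each
    ``m_i`` immediately preceding ``x_i``.

From a scenario the module derives the full set of regressions that the
standard and unexplained-residuals (UR) analyses require: the ``k``
standard models of ``y``, the preparation regressions whose residuals
become UR terms, and the single composite UR model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ScenarioKind",
    "PlanRole",
    "AdjustmentMode",
    "ur_plans",
    "ScenarioSpec",
    "PathDAG",
    "RegressionPlan",
    "build_scenario",
    "regression_plans",
    "model_count",
    "load_scenario",
    "to_dagitty",
    "DEFAULT_EDGE_COEF",
]

#: Default path coefficient for every forward edge (standardized scale).
#: Chosen so that the standardized parameterisation (all variables unit
#: variance) is feasible for every scenario at k <= 5: with uniform
#: positive coefficients the implied variance of the linear predictor of
#: late nodes grows roughly quadratically in the number of parents, and
#: 0.15 keeps it below 1 even for the time-varying scenario at k = 5
#: (11 nodes).  Larger uniform values (e.g. 0.3) are infeasible there.
DEFAULT_EDGE_COEF = 0.15


class ScenarioKind(str, Enum):
    NO_CONFOUNDER = "no_confounder"
    TIME_INVARIANT = "time_invariant"
    TIME_VARYING = "time_varying"


class PlanRole(str, Enum):
    STANDARD_SERIES = "standard_series"
    UR_PREP_EXPOSURE = "ur_prep_exposure"
    UR_PREP_CONFOUNDER = "ur_prep_confounder"
    COMPOSITE_UR = "composite_ur"


class AdjustmentMode(str, Enum):
    """How the confounder is treated in the two UR stages.

    ``correct`` adjusts for the confounder both when generating UR
    terms and in the composite model; the ``omit_*`` variants reproduce
    the canonical misadjustments — leaving the confounder out of the
    preparation regressions, out of the composite model, or both —
    whose omitted-variable bias the package quantifies.
    """

    CORRECT = "correct"
    OMIT_CONFOUNDER_IN_PREP = "omit_confounder_in_prep"
    OMIT_CONFOUNDER_IN_COMPOSITE = "omit_confounder_in_composite"
    OMIT_BOTH = "omit_both"


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one of the three causal scenarios.

    Parameters
    ----------
    kind
        Which confounding structure is modelled.
    k
        Number of exposure time points (k >= 2).
    exposure_name, outcome_name, confounder_name
        Base identifiers; time-indexed columns are formed as e.g. ``x1``.
    """

    kind: ScenarioKind
    k: int
    exposure_name: str = "x"
    outcome_name: str = "y"
    confounder_name: str = "m"

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScenarioKind(self.kind))
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        names = {self.exposure_name, self.outcome_name, self.confounder_name}
        if len(names) != 3:
            raise ValueError("exposure, outcome and confounder names must differ")

    # -- column naming ------------------------------------------------
    def exposure(self, i: int) -> str:
        return f"{self.exposure_name}{i}"

    def confounder(self, i: int | None = None) -> str:
        if self.kind is ScenarioKind.TIME_INVARIANT:
            return self.confounder_name
        if i is None:
            raise ValueError("time-varying confounder requires a time index")
        return f"{self.confounder_name}{i}"

    def ur_name(self, column: str) -> str:
        """Name of the UR column derived for an observed column."""
        return f"e_{column}"

    @property
    def nodes(self) -> tuple[str, ...]:
        """All observed variables in temporal order (outcome last)."""
        k, y = self.k, self.outcome_name
        xs = [self.exposure(i) for i in range(1, k + 1)]
        if self.kind is ScenarioKind.NO_CONFOUNDER:
            return tuple(xs + [y])
        if self.kind is ScenarioKind.TIME_INVARIANT:
            return tuple([self.confounder_name] + xs + [y])
        inter = itertools.chain.from_iterable(
            (self.confounder(i), self.exposure(i)) for i in range(1, k + 1)
        )
        return tuple(list(inter) + [y])


@dataclass(frozen=True)
class RegressionPlan:
    """One regression in the standard or UR procedure."""

    response: str
    covariates: tuple[str, ...]
    role: PlanRole
    index: int = 0  # time index i for standard/prep plans; k for composite

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError(f"duplicate covariates in plan for {self.response}")
        if self.response in self.covariates:
            raise ValueError(f"{self.response} cannot be its own covariate")


@dataclass(frozen=True)
class PathDAG:
    """Temporally ordered DAG with path coefficients on its edges.

    ``nodes`` are listed in temporal order; every edge must point from an
    earlier node to a strictly later one, so the graph is acyclic by
    construction.  ``residual_sd`` gives the standard deviation of each
    node's independent unexplained-cause term (for exogenous nodes this
    is simply the node's own SD).
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[str, str], float]
    residual_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        order = {v: j for j, v in enumerate(self.nodes)}
        if len(order) != len(self.nodes):
            raise ValueError("duplicate node names")
        for (a, b), coef in self.edges.items():
            if a not in order or b not in order:
                raise ValueError(f"edge {a}->{b} references unknown node")
            if order[a] >= order[b]:
                raise ValueError(f"edge {a}->{b} violates temporal order")
            if not np.isfinite(coef):
                raise ValueError(f"edge {a}->{b} has non-finite coefficient")
        for v in self.nodes:
            sd = self.residual_sd.get(v)
            if sd is None or not np.isfinite(sd) or sd < 0:
                raise ValueError(f"node {v} needs a finite residual_sd >= 0")

    # -- graph helpers ------------------------------------------------
    def order(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def parents(self, node: str) -> tuple[str, ...]:
        j = self.order(node)
        return tuple(v for v in self.nodes[:j] if (v, node) in self.edges)

    def coefficient(self, source: str, target: str) -> float:
        return float(self.edges.get((source, target), 0.0))

    def replace(self, **kw) -> "PathDAG":
        return replace(self, **kw)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (a, b), coef in self.edges.items():
            g.add_edge(a, b, coefficient=float(coef))
        return g


def _forward_edges(nodes: Sequence[str]) -> list[tuple[str, str]]:
    return [(a, b) for a, b in itertools.combinations(nodes, 2)]


def build_scenario(
    spec: ScenarioSpec,
    coefficients: Mapping[tuple[str, str], float] | float | None = None,
) -> PathDAG:
    """Construct the forwardly saturated DAG for a scenario.

    Parameters
    ----------
    spec
        Scenario description.
    coefficients
        ``None`` uses :data:`DEFAULT_EDGE_COEF` on every edge; a float
        applies uniformly; a mapping overrides individual ``(source,
        target)`` edges (unknown keys are an error), remaining edges
        keeping the default.

    Every residual SD is initially 1; use
    :func:`urmodels.sem_sim.solve_standardized` for the unit-variance
    parameterisation used by the path-coefficient method.
    """
    nodes = spec.nodes
    edge_list = _forward_edges(nodes)
    if coefficients is None or isinstance(coefficients, (int, float)):
        base = DEFAULT_EDGE_COEF if coefficients is None else float(coefficients)
        edges = {e: base for e in edge_list}
    else:
        known = set(edge_list)
        unknown = set(coefficients) - known
        if unknown:
            raise ValueError(f"unknown edge keys: {sorted(unknown)}")
        edges = {e: float(coefficients.get(e, DEFAULT_EDGE_COEF)) for e in edge_list}
    dag = PathDAG(nodes=nodes, edges=edges, residual_sd={v: 1.0 for v in nodes})
    if coefficients is None:
        # defaults must admit the unit-variance parameterisation
        from .sem_sim import solve_standardized

        solve_standardized(dag)
    return dag


def regression_plans(spec: ScenarioSpec) -> list[RegressionPlan]:
    """All regressions of the standard and UR procedures, in fit order.

    Returns the ``k`` standard models of the outcome, then the
    preparation regressions in temporal order, then the composite UR
    model.  Covariate sets implement correct confounder adjustment:

    * every standard model ``i`` adjusts ``y`` for all measurements of
      exposure (and confounder, where present) up to time ``i``;
    * the preparation regression for ``x_i`` adjusts for all previous
      exposures plus ``m`` (time-invariant) or ``m1..m_i`` including the
      contemporaneous confounder (time-varying);
    * the time-varying scenario additionally residualises each ``m_i``
      on everything before it, and its composite model regresses ``y``
      on ``m1, x1`` and the interleaved UR terms.
    """
    k, y = spec.k, spec.outcome_name
    x = spec.exposure
    plans: list[RegressionPlan] = []

    if spec.kind is ScenarioKind.NO_CONFOUNDER:
        std_prefix: list[str] = []
        prep_extra: list[list[str]] = [[] for _ in range(k + 1)]
        composite = [x(1)] + [spec.ur_name(x(i)) for i in range(2, k + 1)]
    elif spec.kind is ScenarioKind.TIME_INVARIANT:
        m = spec.confounder()
        std_prefix = [m]
        prep_extra = [[m] for _ in range(k + 1)]
        composite = [m, x(1)] + [spec.ur_name(x(i)) for i in range(2, k + 1)]
    else:
        m = spec.confounder
        std_prefix = []
        composite = [m(1), x(1)]
        for i in range(2, k + 1):
            composite += [spec.ur_name(m(i)), spec.ur_name(x(i))]

    for i in range(1, k + 1):
        if spec.kind is ScenarioKind.TIME_VARYING:
            cov = list(
                itertools.chain.from_iterable(
                    (spec.confounder(j), x(j)) for j in range(1, i + 1)
                )
            )
        else:
            cov = std_prefix + [x(j) for j in range(1, i + 1)]
        plans.append(
            RegressionPlan(y, tuple(cov), PlanRole.STANDARD_SERIES, index=i)
        )

    for i in range(2, k + 1):
        if spec.kind is ScenarioKind.TIME_VARYING:
            m = spec.confounder
            prev_m = [m(j) for j in range(1, i)]
            prev_x = [x(j) for j in range(1, i)]
            plans.append(
                RegressionPlan(
                    m(i),
                    tuple(prev_m + prev_x),
                    PlanRole.UR_PREP_CONFOUNDER,
                    index=i,
                )
            )
            plans.append(
                RegressionPlan(
                    x(i),
                    tuple(prev_m + [m(i)] + prev_x),
                    PlanRole.UR_PREP_EXPOSURE,
                    index=i,
                )
            )
        else:
            cov = prep_extra[i] + [x(j) for j in range(1, i)]
            plans.append(
                RegressionPlan(x(i), tuple(cov), PlanRole.UR_PREP_EXPOSURE, index=i)
            )

    plans.append(RegressionPlan(y, tuple(composite), PlanRole.COMPOSITE_UR, index=k))
    return plans


def ur_plans(
    spec: ScenarioSpec, mode: AdjustmentMode | str = AdjustmentMode.CORRECT
) -> tuple[list[RegressionPlan], RegressionPlan]:
    """Preparation plans and the composite plan under an adjustment mode.

    Under ``correct`` these are the canonical UR-procedure plans.  The
    misadjustment modes drop the confounder columns from the indicated
    stage: ``omit_confounder_in_prep`` removes them from the exposure
    preparation regressions, ``omit_confounder_in_composite`` removes
    the confounder terms (``m``, or ``m1`` plus all ``e_m`` terms) from
    the composite model, and ``omit_both`` does both.  Confounder UR
    terms whose only consumer is an omitted composite column are not
    generated at all.  Misadjustment modes are meaningless — and
    rejected — for the no-confounder scenario.
    """
    mode = AdjustmentMode(mode)
    if mode is not AdjustmentMode.CORRECT and spec.kind is ScenarioKind.NO_CONFOUNDER:
        raise ValueError(f"mode {mode.value!r} requires a scenario with a confounder")

    plans = regression_plans(spec)
    preps = [p for p in plans if p.role in (PlanRole.UR_PREP_EXPOSURE, PlanRole.UR_PREP_CONFOUNDER)]
    composite = next(p for p in plans if p.role is PlanRole.COMPOSITE_UR)

    if spec.kind is ScenarioKind.NO_CONFOUNDER or mode is AdjustmentMode.CORRECT:
        return preps, composite

    if spec.kind is ScenarioKind.TIME_INVARIANT:
        conf_cols = {spec.confounder()}
    else:
        conf_cols = {spec.confounder(i) for i in range(1, spec.k + 1)}
    conf_terms = conf_cols | {spec.ur_name(c) for c in conf_cols}

    omit_prep = mode in (AdjustmentMode.OMIT_CONFOUNDER_IN_PREP, AdjustmentMode.OMIT_BOTH)
    omit_comp = mode in (AdjustmentMode.OMIT_CONFOUNDER_IN_COMPOSITE, AdjustmentMode.OMIT_BOTH)

    if omit_comp:
        composite = replace(
            composite,
            covariates=tuple(c for c in composite.covariates if c not in conf_terms),
        )
        preps = [p for p in preps if p.role is not PlanRole.UR_PREP_CONFOUNDER]
    if omit_prep:
        preps = [
            replace(p, covariates=tuple(c for c in p.covariates if c not in conf_cols))
            if p.role is PlanRole.UR_PREP_EXPOSURE
            else p
            for p in preps
        ]
    return preps, composite


def model_count(spec: ScenarioSpec) -> int:
    """Number of regressions the UR procedure constructs.

    ``k`` for the no-confounder and time-invariant scenarios (k - 1
    preparation regressions plus one composite model); ``2k - 1`` when
    the confounder is time-varying (2(k - 1) preparation regressions
    plus the composite).
    """
    if spec.kind is ScenarioKind.TIME_VARYING:
        return 2 * spec.k - 1
    return spec.k


# ---------------------------------------------------------------------------
# configuration I/O


def load_scenario(path: str | Path) -> tuple[ScenarioSpec, PathDAG]:
    """Read a scenario configuration (YAML/JSON dialect).

    Recognised keys: ``kind``, ``k``, optional ``names`` (mapping with
    ``exposure`` / ``outcome`` / ``confounder``), optional ``edges`` — a
    list of ``{from, to, coef}`` records overriding the default path
    coefficient on individual edges.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "kind" not in cfg or "k" not in cfg:
        raise ValueError(f"{path}: scenario config must define 'kind' and 'k'")
    names = cfg.get("names") or {}
    spec = ScenarioSpec(
        kind=cfg["kind"],
        k=int(cfg["k"]),
        exposure_name=names.get("exposure", "x"),
        outcome_name=names.get("outcome", "y"),
        confounder_name=names.get("confounder", "m"),
    )
    coefficients = None
    if cfg.get("edges"):
        coefficients = {
            (str(e["from"]), str(e["to"])): float(e["coef"]) for e in cfg["edges"]
        }
    return spec, build_scenario(spec, coefficients)


def to_dagitty(dag: PathDAG) -> str:
    """Export a DAG in dagitty's plain-text syntax for external checking."""
    lines = ["dag {"]
    lines += [f"  {v}" for v in dag.nodes]
    for (a, b) in sorted(dag.edges, key=lambda e: (dag.order(e[0]), dag.order(e[1]))):
        lines.append(f"  {a} -> {b} [beta={dag.edges[(a, b)]:g}]")
    lines.append("}")
    return "\n".join(lines)
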