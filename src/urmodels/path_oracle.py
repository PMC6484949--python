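"""True causal effects on a parameterised DAG by the method of path coefficients.

On a standardized linear DAG (every variable with population variance
one) the total causal effect of one node on a later node is the sum,
over all directed paths between them, of the product of the path
coefficients along each path.  This module computes those effects
exactly and also solves population least-squares problems from the
implied covariance, providing the independent oracle against which all
finite-sample estimates in the package are checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .scenario_dag import PathDAG
from .sem_sim import implied_covariance

__all__ = [
    "EffectDecomposition",
    "enumerate_paths",
    "total_effect",
    "regression_oracle",
    "attach_residual_node",
    "RESIDUAL_PREFIX",
]

#: Materialised residual nodes are named with this prefix and are exempt
#: from the unit-variance check (their variance is the residual variance
#: of the variable they feed; the unit edge into that variable keeps all
#: path sums unchanged).
RESIDUAL_PREFIX = "e_"


@dataclass(frozen=True)
class EffectDecomposition:
    """A total effect split into its direct and indirect path components."""

    source: str
    target: str
    direct: float
    indirect_paths: tuple[tuple[tuple[str, ...], float], ...]
    total: float

    @property
    def n_paths(self) -> int:
        return len(self.indirect_paths) + (1 if self.direct != 0.0 else 0)


def enumerate_paths(dag: PathDAG, source: str, target: str) -> list[tuple[str, ...]]:
    """All directed paths from ``source`` to ``target``.

    Paths visit nodes in strictly increasing temporal order (the graph
    is forward-directed) and are returned in deterministic
    lexicographic order of their temporal index sequences.
    """
    if source == target:
        raise ValueError("source and target must differ")
    dag.order(source), dag.order(target)  # raise KeyError on unknown nodes
    g = dag.to_networkx()
    paths = [tuple(p) for p in nx.all_simple_paths(g, source, target)]
    return sorted(paths, key=lambda p: tuple(dag.order(v) for v in p))


def _require_standardized(dag: PathDAG) -> None:
    diag = np.diag(implied_covariance(dag).to_numpy())
    for v, var in zip(dag.nodes, diag):
        if v.startswith(RESIDUAL_PREFIX):
            continue
        if abs(var - 1.0) > 1e-9:
            raise ValueError(
                f"total_effect requires a standardized DAG; node {v!r} has "
                f"implied variance {var:.6f} (use sem_sim.solve_standardized)"
            )


def total_effect(dag: PathDAG, source: str, target: str) -> EffectDecomposition:
    """Total causal effect of ``source`` on ``target`` via path coefficients.

    The DAG must be standardized (all observed variables unit
    variance).  Path products are summed in deterministic lexicographic
    path order so floating results are reproducible.
    """
    _require_standardized(dag)
    direct = dag.coefficient(source, target)
    indirect = []
    total = 0.0
    for path in enumerate_paths(dag, source, target):
        prod = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prod *= dag.coefficient(a, b)
        total += prod
        if len(path) > 2:
            indirect.append((path, prod))
    return EffectDecomposition(
        source=source,
        target=target,
        direct=float(direct),
        indirect_paths=tuple(indirect),
        total=float(total),
    )


def regression_oracle(
    dag: PathDAG, response: str, covariates: list[str] | tuple[str, ...]
) -> dict[str, float]:
    """Population OLS coefficients from the implied covariance.

    Solves the population normal equations
    ``Cov(C, C) beta = Cov(C, response)``; this is the probability
    limit of the corresponding sample regression and serves as the
    independent brute-force oracle for every estimation check
    (including exact asymptotic omitted-variable bias).
    """
    sigma = implied_covariance(dag)
    cc = sigma.loc[list(covariates), list(covariates)].to_numpy()
    cy = sigma.loc[list(covariates), response].to_numpy()
    # fail loudly on a singular covariate covariance
    if np.linalg.matrix_rank(cc) < len(covariates):
        raise np.linalg.LinAlgError(
            f"covariate covariance is singular for {list(covariates)}"
        )
    beta = np.linalg.solve(cc, cy)
    return {c: float(b) for c, b in zip(covariates, beta)}


def attach_residual_node(dag: PathDAG, variable: str) -> tuple[PathDAG, str]:
    """Materialise a variable's unexplained-cause term as a graph node.

    Inserts ``e_<variable>`` immediately before ``variable`` with a
    unit-coefficient edge into it; the variable's residual SD moves to
    the new node (the variable's own becomes 0).  Mirrors the treatment
    of residual terms as instrumental-variable-like nodes: the total
    effect of ``e_<variable>`` on any later node equals that of
    ``variable`` itself.
    """
    name = f"{RESIDUAL_PREFIX}{variable}"
    if name in dag.nodes:
        raise ValueError(f"node {name!r} already exists")
    j = dag.order(variable)
    nodes = dag.nodes[:j] + (name,) + dag.nodes[j:]
    edges = dict(dag.edges)
    edges[(name, variable)] = 1.0
    residual_sd = dict(dag.residual_sd)
    residual_sd[name] = residual_sd[variable]
    residual_sd[variable] = 0.0
    return PathDAG(nodes=nodes, edges=edges, residual_sd=residual_sd), name
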