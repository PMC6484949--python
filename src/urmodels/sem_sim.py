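"""Linear-Gaussian structural equation simulation on a :class:`PathDAG`.

Each node is generated in temporal order as a linear combination of its
parents plus an independent Gaussian unexplained-cause term.  The module
also provides the exact population covariance implied by the SEM and the
standardized (unit-variance) parameterisation assumed by the method of
path coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .scenario_dag import PathDAG

__all__ = [
    "Dataset",
    "StandardizationError",
    "simulate",
    "solve_standardized",
    "implied_covariance",
]


class StandardizationError(ValueError):
    """The unit-variance parameterisation is infeasible for a node."""


@dataclass
class Dataset:
    """An observation-aligned numeric table plus its provenance.

    Thin wrapper over a :class:`pandas.DataFrame` whose columns are the
    observed variables; ``provenance`` records how the data were made
    (generating DAG, seed, standardization flag) or loaded.
    """

    df: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.isna().any().any():
            raise ValueError("Dataset must not contain missing values")
        if len(self.df) < 1:
            raise ValueError("Dataset needs at least one row")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV with a provenance YAML sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        if self.provenance:
            sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
            sidecar.write_text(yaml.safe_dump(self.provenance, sort_keys=False))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
        prov = (
            yaml.safe_load(sidecar.read_text())
            if sidecar.exists()
            else {"source": str(path)}
        )
        return cls(df=df, provenance=prov or {})


def implied_covariance(dag: PathDAG) -> pd.DataFrame:
    """Exact population covariance of all nodes under the linear SEM.

    Computed by forward recursion in temporal order: for node ``v`` with
    parent coefficient vector ``b`` over parents ``P``,
    ``Cov(v, u) = b' Cov(P, u)`` for every earlier ``u`` and
    ``Var(v) = b' Cov(P, P) b + residual_sd(v)**2``.
    """
    nodes = dag.nodes
    idx = {v: j for j, v in enumerate(nodes)}
    n = len(nodes)
    sigma = np.zeros((n, n))
    for j, v in enumerate(nodes):
        parents = dag.parents(v)
        p_idx = [idx[p] for p in parents]
        b = np.array([dag.coefficient(p, v) for p in parents])
        if p_idx:
            cov_pv = b @ sigma[np.ix_(p_idx, range(j))]
            sigma[j, :j] = cov_pv
            sigma[:j, j] = cov_pv
            var_pred = float(b @ sigma[np.ix_(p_idx, p_idx)] @ b)
        else:
            var_pred = 0.0
        sigma[j, j] = var_pred + dag.residual_sd[v] ** 2
    return pd.DataFrame(sigma, index=list(nodes), columns=list(nodes))


def solve_standardized(dag: PathDAG) -> PathDAG:
    """Residual SDs giving every node population variance exactly 1.

    Keeps the path coefficients and solves, node by node in temporal
    order, ``residual variance = 1 - Var(linear predictor)`` where the
    predictor variance is taken under the already-standardized
    covariance of the predecessors.

    Raises
    ------
    StandardizationError
        If some node's implied predictor variance reaches 1, naming the
        offending node.
    """
    nodes = dag.nodes
    idx = {v: j for j, v in enumerate(nodes)}
    n = len(nodes)
    sigma = np.zeros((n, n))
    resid_sd: dict[str, float] = {}
    for j, v in enumerate(nodes):
        parents = dag.parents(v)
        p_idx = [idx[p] for p in parents]
        b = np.array([dag.coefficient(p, v) for p in parents])
        if p_idx:
            cov_pv = b @ sigma[np.ix_(p_idx, range(j))]
            sigma[j, :j] = cov_pv
            sigma[:j, j] = cov_pv
            var_pred = float(b @ sigma[np.ix_(p_idx, p_idx)] @ b)
        else:
            var_pred = 0.0
        if var_pred >= 1.0:
            raise StandardizationError(
                f"node {v!r}: implied Var(linear predictor) = {var_pred:.4f} >= 1; "
                "unit variance is infeasible with these path coefficients"
            )
        resid_sd[v] = float(np.sqrt(1.0 - var_pred))
        sigma[j, j] = 1.0
    return dag.replace(residual_sd=resid_sd)


def simulate(
    dag: PathDAG,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    standardize: bool = True,
) -> Dataset:
    """Draw ``n`` observations from the linear-Gaussian SEM.

    Nodes are generated in temporal order as ``sum(coef * parent) +
    residual_sd * N(0, 1)``; identical ``(dag, n, seed, standardize)``
    inputs reproduce the dataset bit-for-bit.  With ``standardize`` the
    residual SDs are first re-solved so every node has population
    variance 1 (the parameterisation assumed by the path-coefficient
    oracle); otherwise the DAG's own ``residual_sd`` values are used.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if standardize:
        dag = solve_standardized(dag)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        value = dag.residual_sd[v] * rng.standard_normal(n)
        for p in dag.parents(v):
            value += dag.coefficient(p, v) * cols[p]
        cols[v] = value
    seed_repr = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
    provenance = {
        "generator": "urmodels.sem_sim.simulate",
        "nodes": list(dag.nodes),
        "n": int(n),
        "seed": repr(seed_repr),
        "standardize": bool(standardize),
    }
    return Dataset(df=pd.DataFrame(cols), provenance=provenance)
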