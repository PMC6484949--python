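"""Reported vs. bootstrap standard errors for UR-model coefficients.

The UR terms entering a composite model are generated regressors:
estimates whose own sampling variability the classical reported SEs
ignore.  The consequence is an artefactual SE reduction for the
baseline-exposure coefficient — the composite model conditions on
residuals built from *future* measurements — while the SE reported for
each UR term matches the corresponding standard model exactly (their
designs span the same column space).

This module provides (a) a case-resampling bootstrap that regenerates
the UR terms inside every resample, which is what propagates the
generated-regressor variability and restores honest SEs, and (b) a
Monte-Carlo experiment comparing reported and bootstrap SEs across
simulated replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression_core import as_frame
from .scenario_dag import AdjustmentMode, PathDAG, ScenarioSpec, ur_plans
from .sem_sim import Dataset, simulate

__all__ = ["BootstrapResult", "SEComparisonSummary", "bootstrap_se", "se_comparison_experiment"]

_MAX_REDRAWS = 100


@dataclass
class BootstrapResult:
    """Bootstrap SEs (SD of coefficients across case resamples)."""

    coefficient_ids: list[str]
    bootstrap_se: dict[str, float]
    reps: int
    seed: int | None
    redraws: int = 0


@dataclass
class SEComparisonSummary:
    """Aggregate of the reported/bootstrap SE comparison experiment.

    ``table`` has one row per total-effect coefficient ``x_i`` with the
    mean and SD (across replicates) of: the reported SE of ``x_i`` in
    standard model ``i``; the reported SE of its composite-UR
    counterpart (``x1`` itself for i = 1, ``e_xi`` otherwise); and the
    bootstrap SE of that counterpart.  ``records`` keeps the
    per-replicate values.
    """

    table: pd.DataFrame
    records: pd.DataFrame
    replicates: int
    n: int
    boot_reps: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path=None):
        """Violin plots of the three SE distributions per coefficient."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        coefs = self.table["coefficient"].tolist()
        fig, axes = plt.subplots(1, len(coefs), figsize=(4 * len(coefs), 4), squeeze=False)
        for ax, coef in zip(axes[0], coefs):
            sub = self.records[self.records["coefficient"] == coef]
            data = [sub["se_standard"], sub["se_ur_reported"], sub["se_ur_bootstrap"]]
            ax.violinplot([np.asarray(d) for d in data], showmeans=True)
            ax.set_xticks([1, 2, 3])
            ax.set_xticklabels(["standard\nreported", "UR\nreported", "UR\nbootstrap"])
            ax.set_title(coef)
            ax.set_ylabel("standard error")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _lstsq_coef(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Coefficients and rank of an intercept-augmented least squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    return beta, rank


def _resample_coefficients(
    raw: np.ndarray,
    col_idx: dict[str, int],
    prep_plans,
    composite_plan,
    spec: ScenarioSpec,
    rows: np.ndarray,
) -> np.ndarray | None:
    """Composite coefficients on one row resample; None if rank deficient.

    UR terms are re-derived from scratch inside the resample — this is
    what propagates the generated-regressor variability into the
    bootstrap distribution.
    """
    n = len(rows)
    sample = raw[rows]
    cols: dict[str, np.ndarray] = {name: sample[:, j] for name, j in col_idx.items()}
    ones = np.ones(n)
    for plan in prep_plans:
        design = np.column_stack([ones] + [cols[c] for c in plan.covariates])
        y = cols[plan.response]
        beta, rank = _lstsq_coef(design, y)
        if rank < design.shape[1]:
            return None
        cols[spec.ur_name(plan.response)] = y - design @ beta
    design = np.column_stack([ones] + [cols[c] for c in composite_plan.covariates])
    beta, rank = _lstsq_coef(design, cols[composite_plan.response])
    if rank < design.shape[1]:
        return None
    return beta[1:]  # drop intercept


def bootstrap_se(
    data: Dataset | pd.DataFrame,
    spec: ScenarioSpec,
    reps: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    mode: AdjustmentMode | str = AdjustmentMode.CORRECT,
) -> BootstrapResult:
    """Case-resampling bootstrap SEs for the composite UR coefficients.

    Rows are resampled with replacement; within each resample the UR
    terms are regenerated and the composite model refit; the SE of each
    coefficient is the SD of its estimates across resamples.  A
    rank-deficient resample is redrawn (redraws are counted and capped).
    Deterministic given ``seed``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    mode = AdjustmentMode(mode)
    df = as_frame(data)
    prep_plans, composite_plan = ur_plans(spec, mode)
    raw_cols = [c for c in df.columns if not c.startswith("e_")]
    raw = df[raw_cols].to_numpy(dtype=float)
    col_idx = {name: j for j, name in enumerate(raw_cols)}
    n = len(df)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    names = list(composite_plan.covariates)
    draws = np.empty((reps, len(names)))
    redraws = 0
    for r in range(reps):
        while True:
            rows = rng.integers(0, n, size=n)
            beta = _resample_coefficients(
                raw, col_idx, prep_plans, composite_plan, spec, rows
            )
            if beta is not None:
                break
            redraws += 1
            if redraws > _MAX_REDRAWS:
                raise RuntimeError(
                    f"exceeded {_MAX_REDRAWS} redraws of rank-deficient resamples"
                )
        draws[r] = beta
    sd = draws.std(axis=0, ddof=1)
    seed_id = seed if isinstance(seed, (int, np.integer)) else None
    return BootstrapResult(
        coefficient_ids=names,
        bootstrap_se={name: float(s) for name, s in zip(names, sd)},
        reps=reps,
        seed=seed_id,
        redraws=redraws,
    )


def se_comparison_experiment(
    dag: PathDAG,
    spec: ScenarioSpec,
    replicates: int = 200,
    n: int = 1000,
    boot_reps: int = 200,
    seed: int = 0,
    standardize: bool = True,
) -> SEComparisonSummary:
    """Monte-Carlo comparison of reported and bootstrap SEs.

    Simulates ``replicates`` non-overlapping samples of ``n``
    observations from ``dag``; in each, fits the standard series and the
    composite UR model, records the reported SE of every total-effect
    coefficient and its UR counterpart, and bootstraps the UR model.
    Each replicate runs on an independent substream spawned from
    ``seed``, so results do not depend on execution order and replicate
    ``r`` is reproducible in isolation.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    from .estimators import URRegressor
    from .regression_core import standard_series

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(replicates)
    rows = []
    for r, child in enumerate(children):
        sim_ss, boot_ss = child.spawn(2)
        data = simulate(dag, n=n, seed=sim_ss, standardize=standardize)
        series = standard_series(data, spec)
        ur = URRegressor(
            scenario=spec.kind.value,
            k=spec.k,
            exposure_name=spec.exposure_name,
            outcome_name=spec.outcome_name,
            confounder_name=spec.confounder_name,
        ).fit(data.df)
        boot = bootstrap_se(data, spec, reps=boot_reps, seed=np.random.default_rng(boot_ss))
        for i in range(1, spec.k + 1):
            xi = spec.exposure(i)
            counterpart = xi if i == 1 else spec.ur_name(xi)
            rows.append(
                {
                    "replicate": r,
                    "coefficient": xi,
                    "ur_counterpart": counterpart,
                    "se_standard": series.fits[i - 1].reported_se[xi],
                    "se_ur_reported": ur.se_[counterpart],
                    "se_ur_bootstrap": boot.bootstrap_se[counterpart],
                }
            )
    records = pd.DataFrame(rows)
    agg = (
        records.groupby("coefficient", sort=False)
        .agg(
            mean_se_standard=("se_standard", "mean"),
            sd_se_standard=("se_standard", "std"),
            mean_se_ur_reported=("se_ur_reported", "mean"),
            sd_se_ur_reported=("se_ur_reported", "std"),
            mean_se_ur_bootstrap=("se_ur_bootstrap", "mean"),
            sd_se_ur_bootstrap=("se_ur_bootstrap", "std"),
        )
        .reset_index()
    )
    agg["replicates"] = replicates
    agg["n"] = n
    return SEComparisonSummary(
        table=agg, records=records, replicates=replicates, n=n, boot_reps=boot_reps
    )
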