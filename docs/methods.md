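# Methods

## Model

All scenarios are linear-Gaussian structural equation models on a
forwardly saturated DAG: nodes in temporal order, every node possibly
affecting every later node, and each endogenous node equal to a linear
combination of its parents plus an independent Gaussian
unexplained-cause term. Three node layouts are supported:

| scenario         | nodes (temporal order)            |
|------------------|-----------------------------------|
| `no_confounder`  | `x1, ..., xk, y`                  |
| `time_invariant` | `m, x1, ..., xk, y`               |
| `time_varying`   | `m1, x1, m2, x2, ..., mk, xk, y`  |

Two conventions are fixed here because the layout alone does not decide
them: each time-varying confounder measurement `m_i` *precedes* its
contemporaneous exposure `x_i` (so the edge `m_i -> x_i` exists, and the
preparation regression for `x_i` adjusts for `m_i`); and `m` / `m1` are
exogenous — nothing on the graph causes them beyond their own residual
term. The outcome is terminal: no edges leave `y`.

Path coefficients live on the standardized scale. `solve_standardized`
keeps the coefficients and re-solves the residual SDs node-by-node so
every variable has population variance exactly one
(`residual variance = 1 − Var(linear predictor)`, with the predictor
variance taken under the already-standardized covariance of the
predecessors). This parameterisation is what makes the path-coefficient
calculus exact: the total causal effect of `a` on `b` is the sum over
directed paths of the product of edge coefficients, and it equals the
population regression coefficient of the most recent exposure in a
correctly adjusted model. Standardization is infeasible when some
node's implied predictor variance reaches 1; the error names the node.

## Parameters and defaults

* **Default edge coefficient: 0.15** on every forward edge. With
  uniform positive coefficients on a saturated graph, the implied
  predictor variance of late nodes grows roughly quadratically in the
  number of parents; 0.15 is the round value that keeps the
  standardized parameterisation feasible for every scenario at k ≤ 5
  (the time-varying scenario at k = 5 has 11 nodes, the worst case).
  Larger uniform values — 0.3, say — are already infeasible there.
  Feasibility of the defaults is asserted at DAG construction time.
* **k (exposure time points):** ≥ 2; the test grid runs k = 2..5, with
  k = 6 exercised only for model-count accounting (no simulation).
* **Simulation sizes.** Property checks use n = 500 (the identities are
  exact at any n; the size only controls runtime). Bias experiments use
  n = 100 000 so sampling noise is small against the analytic
  omitted-variable bias. The SE experiment defaults to 200 replicates
  of n = 1000 with 200 bootstrap resamples each — the package's desk
  scale; the experiment function takes all three as parameters for
  larger runs (e.g. 1000/1000/1000).
* **SEs:** classical homoskedastic OLS standard errors (denominator
  `n − p − 1`) throughout, since the reported-vs-honest-SE contrast is
  the object of study. Robust/sandwich SEs are out of scope.

## The UR procedure and its guarantees

For `i = 2..k` the preparation regression of `x_i` on everything
temporally before it (and, in the time-varying scenario, also on the
contemporaneous `m_i`) yields the UR column `e_xi`; a time-varying
confounder is residualised the same way (`m_i` on all earlier `m` and
`x`), `e_m_i` before `e_x_i`. The composite model regresses `y` on the
baseline term(s) and all UR columns. Preparation fits are always
in-sample on the analysis data: residuals from the same rows the
composite model uses, never out-of-sample predictions.

Because every UR column is an OLS residual, it is exactly orthogonal
(in-sample) to the covariates of its preparation fit, and hence to all
earlier UR columns (which are linear combinations of those covariates).
Properties (i)–(iii) follow by direct substitution and hold in exact
arithmetic; the default verification tolerance of **1e-10** (relative
on coefficients, absolute on fitted values) only absorbs floating
error. The property report also carries the maximum absolute sample
correlation among composite covariate pairs involving a UR term, which
should sit at numerical zero (≤ 1e-8) under correct adjustment.

Misadjustment is exposed as an enumerated mode, not free-form covariate
editing, so each variant is a reproducible one-flag experiment:
`omit_confounder_in_prep` drops the confounder columns from the
exposure preparation regressions, `omit_confounder_in_composite` drops
the confounder terms from the composite model (for a time-varying
confounder: `m1` and all `e_m` terms, whose preparation fits are then
skipped as their output would be unused), `omit_both` does both. The
baseline confounder itself is never residualised — it enters the
composite raw.

Two subtleties about degenerate cases, found while validating:

* When all confounder edges are zero, omission is harmless only
  *asymptotically*: the population composite coefficients equal the
  total effects exactly, but in finite samples a misadjusted UR column
  retains a chance in-sample correlation with the (inert) confounder,
  so the coefficient identities hold to O(1/√n), not to 1e-10.
* Severing `x1 -> x2` does **not** equalize the composite and standard
  SEs for `x1`: conditioning on `e_x2` reduces residual variance
  whenever `x2` affects `y`, regardless of exposure tracking. The SE
  reduction disappears when `x2 -> y` is zero.

## Population algebra (the independent oracle)

`implied_covariance` computes the exact covariance of all nodes by
forward recursion; `regression_oracle` solves population normal
equations from it; `total_effect` enumerates directed paths
(lexicographic order of temporal index sequences, so floating sums are
reproducible) and sums coefficient products. Residual terms can be
materialised as explicit nodes with a unit edge into their variable,
which shows the instrumental-variable-like character of UR terms: the
total effect from `e_xi` equals the total effect from `x_i`.

`population_ur_coefficients` extends the oracle to the UR procedure
itself: each UR column is represented as the population least-squares
residual of its preparation regression — a linear combination of
observed nodes — and the composite coefficients solve the population
normal equations over those combinations. Under correct adjustment this
reproduces the total effects; under a misadjustment mode the departure
is the exact asymptotic omitted-variable bias, against which the
large-sample empirical bias is checked (agreement within 10% at
n = 100 000, where the residual discrepancy is pure sampling noise).

## Simulation and randomness

Nodes are generated in temporal order with `numpy.random.default_rng`;
identical inputs give bit-identical datasets. Multi-replicate
experiments spawn one `SeedSequence` child per replicate, so replicate
`r` is reproducible without generating replicates `1..r−1` and summary
statistics do not depend on execution order. Within a replicate the
simulation and the bootstrap draw from separate spawned substreams.

The generator emulates idealised study conditions: exactly linear
structural equations, Gaussian unexplained causes, no missingness, no
measurement error, no unobserved confounding (all residual terms
mutually independent). Passing tests therefore demonstrate the algebra
and the asymptotics of the method under its own assumptions; they say
nothing about robustness to nonlinearity, non-Gaussian noise, or
informative dropout in real cohort data — all of which are explicitly
out of scope.

## Bootstrap

The bootstrap resamples whole rows (cases) with replacement and
regenerates the UR columns from scratch inside every resample before
refitting the composite model; the SE is the SD of each coefficient
across resamples. Regeneration is the essential choice: it is what
propagates the sampling variability of the generated regressors, which
the classical reported SEs ignore. A rank-deficient resample is redrawn
(capped at 100 redraws, then an error). The resample path solves for
coefficients only via `numpy.linalg.lstsq` — no SEs are needed inside
the loop — and is cross-checked in the test suite against the
statsmodels-backed full fitting route on identical rows.

## Numerical choices and edge cases

* Collinearity in any design matrix is a hard error naming the
  dependent columns; silent dropping would corrupt the orthogonality
  the UR construction relies on.
* Every model includes an intercept, so UR columns have exact sample
  mean zero.
* `fit_ols` requires `n > p + 1`; datasets must be free of missing
  values (no imputation is attempted).
* Scenario configs are YAML (`kind`, `k`, optional `names` and per-edge
  `edges` overrides); DAGs export to dagitty plain-text syntax for
  cross-checking in external DAG tools.

## Limitations

Only the three canonical scenarios are supported — arbitrary DAGs with
latent confounding or non-saturated structure, and general
backdoor-set discovery, are non-goals. The analytic magnitude of the
reported-SE bias is not derived; the package demonstrates and corrects
it numerically. Alternative longitudinal approaches (multilevel, latent
growth curve, growth mixture, G-methods) and deviating UR-construction
variants found in the applied literature are out of scope.
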