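import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urmodels import (
    ScenarioSpec,
    build_scenario,
    check_properties,
    fit_composite_ur,
    implied_covariance,
    make_ur_terms,
    population_ur_coefficients,
    regression_plans,
    simulate,
    solve_standardized,
    standard_series,
    total_effect,
)
from urmodels.scenario_dag import PlanRole

from conftest import SCENARIOS


class TestMakeURTerms:
    def test_ur_columns_are_centred_and_orthogonal(self, fig1_data, fig1_spec):
        dec = make_ur_terms(fig1_data, fig1_spec)
        e = dec.ur_columns["e_x2"]
        assert abs(e.mean()) < 1e-12
        assert abs(np.corrcoef(fig1_data.df["x1"], e)[0, 1]) < 1e-12

    def test_time_varying_full_orthogonality(self):
        spec = ScenarioSpec("time_varying", k=2)
        data = simulate(build_scenario(spec), n=500, seed=12)
        dec = make_ur_terms(data, spec)
        e_x2 = dec.ur_columns["e_x2"]
        for col in ["m1", "x1", "m2"]:
            assert abs(np.corrcoef(data.df[col], e_x2)[0, 1]) < 1e-10
        assert abs(np.corrcoef(dec.ur_columns["e_m2"], e_x2)[0, 1]) < 1e-10

    def test_omitted_confounder_leaves_residual_confounded(self, confounded_dag):
        # analytic population correlation between e_x2 (built without m) and m
        spec, dag = confounded_dag
        sigma = implied_covariance(solve_standardized(dag))
        c = sigma.loc["x1", "x2"] / sigma.loc["x1", "x1"]
        cov_em = sigma.loc["m", "x2"] - c * sigma.loc["m", "x1"]
        var_e = (
            sigma.loc["x2", "x2"]
            - 2 * c * sigma.loc["x1", "x2"]
            + c**2 * sigma.loc["x1", "x1"]
        )
        rho = cov_em / np.sqrt(var_e * sigma.loc["m", "m"])
        assert abs(rho) > 0.2  # the misadjustment leaves real confounding

        data = simulate(dag, n=200_000, seed=13)
        dec = make_ur_terms(data, spec, mode="omit_confounder_in_prep")
        sample_rho = np.corrcoef(data.df["m"], dec.ur_columns["e_x2"])[0, 1]
        assert sample_rho == pytest.approx(rho, abs=0.02)

    def test_mode_requires_confounded_scenario(self, fig1_data, fig1_spec):
        with pytest.raises(ValueError, match="confounder"):
            make_ur_terms(fig1_data, fig1_spec, mode="omit_both")

    def test_row_order_robustness(self, fig1_data, fig1_spec):
        dec = make_ur_terms(fig1_data, fig1_spec)
        perm = np.random.default_rng(0).permutation(fig1_data.n)
        shuffled = fig1_data.df.iloc[perm].reset_index(drop=True)
        dec_shuffled = make_ur_terms(shuffled, fig1_spec)
        inv = np.argsort(perm)
        back = dec_shuffled.ur_columns["e_x2"].to_numpy()[inv]
        assert np.abs(back - dec.ur_columns["e_x2"].to_numpy()).max() < 1e-10


@pytest.mark.parametrize("kind", SCENARIOS)
@pytest.mark.parametrize("k", [2, 3, 4])
class TestPropertiesHold:
    def test_composite_reproduces_standard_series(self, kind, k):
        spec = ScenarioSpec(kind, k=k)
        data = simulate(build_scenario(spec), n=400, seed=100 + k)
        dec = make_ur_terms(data, spec)
        comp = fit_composite_ur(data, dec)
        report = comp.property_report
        assert report.passed
        assert report.prop_i_max_abs_diff < 1e-10
        assert report.prop_ii_abs_diff < 1e-10
        assert all(d < 1e-10 for d in report.prop_iii_abs_diffs.values())
        assert report.max_abs_offdiag_corr < 1e-8


class TestCompositeDetails:
    def test_reparameterisation_recovers_standard_model_k(self):
        # substitute each UR term's preparation-fit expansion back into
        # the composite model; the implied coefficients on the raw
        # columns must equal standard model k's, by direct matrix algebra
        spec = ScenarioSpec("no_confounder", k=3)
        data = simulate(build_scenario(spec), n=300, seed=21)
        dec = make_ur_terms(data, spec)
        comp = fit_composite_ur(data, dec)
        lam = comp.fit.coefficients
        raw = ["x1", "x2", "x3"]
        implied = {c: 0.0 for c in raw}
        implied["x1"] = lam["x1"]
        for fit in dec.prep_fits:  # e_xi = x_i - (g0 + sum_j g_j x_j)
            coef = lam[f"e_{fit.response}"]
            implied[fit.response] += coef
            for cov_name, g in fit.coefficients.items():
                implied[cov_name] -= coef * g
        final = standard_series(data, spec).fits[-1]
        for c in raw:
            assert implied[c] == pytest.approx(final.coefficients[c], abs=1e-10)

    def test_adding_later_ur_term_leaves_earlier_coefficients(self):
        from urmodels.regression_core import fit_ols
        from urmodels.scenario_dag import RegressionPlan

        spec = ScenarioSpec("no_confounder", k=3)
        data = simulate(build_scenario(spec), n=300, seed=22)
        dec = make_ur_terms(data, spec)
        work = pd.concat([data.df, dec.ur_columns], axis=1)
        small = fit_ols(
            work, RegressionPlan("y", ("x1", "e_x2"), PlanRole.COMPOSITE_UR)
        )
        full = fit_ols(
            work, RegressionPlan("y", ("x1", "e_x2", "e_x3"), PlanRole.COMPOSITE_UR)
        )
        for c in ["x1", "e_x2"]:
            assert full.coefficients[c] == pytest.approx(
                small.coefficients[c], abs=1e-12
            )

    def test_mismatched_data_rejected(self, fig1_data, fig1_spec):
        dec = make_ur_terms(fig1_data, fig1_spec)
        with pytest.raises(ValueError, match="different data"):
            fit_composite_ur(fig1_data.df.iloc[:-5], dec)

    def test_harmless_omission_when_confounder_is_inert(self):
        # with every m edge zero, omitting m introduces no bias: the
        # population composite coefficients still equal the total
        # effects exactly; in finite samples the residual chance
        # correlation with m leaves only sampling-noise discrepancies
        spec = ScenarioSpec("time_invariant", k=2)
        coefs = {("m", "x1"): 0.0, ("m", "x2"): 0.0, ("m", "y"): 0.0}
        dag = build_scenario(spec, coefs)
        sdag = solve_standardized(dag)
        truth = total_effect(sdag, "x1", "y").total
        data = simulate(dag, n=2000, seed=30)
        for mode in ["omit_confounder_in_prep", "omit_both"]:
            pop = population_ur_coefficients(sdag, spec, mode)
            assert pop["x1"] == pytest.approx(truth, abs=1e-12)
            dec = make_ur_terms(data, spec, mode=mode)
            comp = fit_composite_ur(data, dec)
            assert (
                comp.property_report.prop_ii_abs_diff
                < 3 * comp.fit.reported_se["x1"]
            )

    def test_misadjusted_composite_is_flagged(self, confounded_dag):
        spec, dag = confounded_dag
        data = simulate(dag, n=50_000, seed=31)
        dec = make_ur_terms(data, spec, mode="omit_both")
        comp = fit_composite_ur(data, dec)
        assert not comp.property_report.passed
        # bias exceeds many reported SEs of the composite x1 coefficient
        assert comp.property_report.prop_ii_abs_diff > 5 * comp.fit.reported_se["x1"]


class TestPopulationCoefficients:
    def test_correct_mode_recovers_total_effects(self, confounded_dag):
        spec, dag = confounded_dag
        sdag = solve_standardized(dag)
        pop = population_ur_coefficients(sdag, spec, "correct")
        assert pop["x1"] == pytest.approx(total_effect(sdag, "x1", "y").total, abs=1e-12)
        assert pop["e_x2"] == pytest.approx(total_effect(sdag, "x2", "y").total, abs=1e-12)

    def test_omitted_variable_bias_matches_large_sample(self, confounded_dag):
        spec, dag = confounded_dag
        sdag = solve_standardized(dag)
        pop = population_ur_coefficients(sdag, spec, "omit_both")
        data = simulate(dag, n=200_000, seed=32)
        dec = make_ur_terms(data, spec, mode="omit_both")
        comp = fit_composite_ur(data, dec)
        assert comp.fit.coefficients["x1"] == pytest.approx(pop["x1"], abs=0.01)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    coefs=st.lists(st.floats(-0.3, 0.3), min_size=6, max_size=6),
    seed=st.integers(0, 2**16),
)
def test_properties_hold_for_random_coefficients(coefs, seed):
    """Properties (i)-(iii) are identities of OLS algebra, whatever the DAG."""
    spec = ScenarioSpec("no_confounder", k=3)
    keys = [("x1", "x2"), ("x1", "x3"), ("x1", "y"), ("x2", "x3"), ("x2", "y"), ("x3", "y")]
    dag = build_scenario(spec, dict(zip(keys, coefs)))
    data = simulate(dag, n=120, seed=seed, standardize=False)
    comp = fit_composite_ur(data, make_ur_terms(data, spec))
    assert comp.property_report.passed
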