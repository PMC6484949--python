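import numpy as np
import pytest

from urmodels import ScenarioSpec, build_scenario, simulate

SCENARIOS = ["no_confounder", "time_invariant", "time_varying"]


@pytest.fixture(scope="session")
def fig1_spec():
    """Two exposure measurements, no additional confounder."""
    return ScenarioSpec("no_confounder", k=2)


@pytest.fixture(scope="session")
def fig1_dag(fig1_spec):
    # uniform 0.3 is feasible for this 3-node graph and gives visible tracking
    return build_scenario(fig1_spec, 0.3)


@pytest.fixture(scope="session")
def fig1_data(fig1_dag):
    return simulate(fig1_dag, n=1000, seed=42)


@pytest.fixture(scope="session")
def confounded_dag():
    """Time-invariant confounder with strong (0.4) confounding edges."""
    spec = ScenarioSpec("time_invariant", k=2)
    coefs = {("m", "x1"): 0.4, ("m", "x2"): 0.4, ("m", "y"): 0.4}
    return spec, build_scenario(spec, coefs)


def make_spec(kind: str, k: int) -> ScenarioSpec:
    return ScenarioSpec(kind, k=k)
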