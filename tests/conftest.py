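import numpy as np
import pytest

from breedopt import (
    DecisionVariable,
    ProblemDefinition,
    SimulationOutcome,
    load_scenario,
)
from breedopt.engine import EvaluatedSetting


@pytest.fixture(scope="session")
def scenario1():
    return load_scenario("scenario1")


@pytest.fixture(scope="session")
def scenario3a():
    return load_scenario("scenario3a")


@pytest.fixture
def quad_problem():
    """Three unconstrained continuous variables on [0, 100] (no budget)."""
    variables = tuple(DecisionVariable(name=n, domain=(0, 100)) for n in ("a", "b", "c"))
    return ProblemDefinition(variables=variables, objective_weight=0.0, name="quad")


@pytest.fixture
def real_problem():
    """Two non-integral continuous variables, handy for pre-rounding checks."""
    variables = tuple(
        DecisionVariable(name=n, domain=(0.0, 100.0), integral=False) for n in ("a", "b")
    )
    return ProblemDefinition(variables=variables, objective_weight=0.0, name="real")


@pytest.fixture
def class_problem():
    """One continuous plus one binary class variable (no budget)."""
    variables = (
        DecisionVariable(name="a", domain=(0, 100)),
        DecisionVariable(name="u", kind="class", categories=(0, 1)),
    )
    return ProblemDefinition(variables=variables, objective_weight=0.0, name="cls")


def make_row(setting, m, iteration=1, seed=0, origin="init", g=None, f=0.0):
    g = m if g is None else g
    outcome = SimulationOutcome(g=g, f=f, m=m, cost=0.0, seed=seed)
    return EvaluatedSetting(setting=setting, outcome=outcome, iteration=iteration, origin=origin)


@pytest.fixture
def row_factory():
    return make_row
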