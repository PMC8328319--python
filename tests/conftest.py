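"""Shared fixtures: the tuned tree, heart parameter sets, and the
(matched stroke volume) paired contractility experiment, which several
test modules interrogate. Session-scoped because each paired run costs
a few seconds of simulation."""

import pytest

from cvwaves import (
    LVParameters,
    PreloadPolicy,
    ScenarioConfig,
    build_fixture_tree,
    run_contractility_experiment,
    sensitivity_suite,
)
from cvwaves.solver import SolverConfig

TARGET_SV = 65.0


@pytest.fixture(scope="session")
def fixture_tree():
    return build_fixture_tree()


@pytest.fixture(scope="session")
def heart_high():
    return LVParameters(Ees=3.0, Vd=-2.0, EDV=97.0)


@pytest.fixture(scope="session")
def heart_low():
    return LVParameters(Ees=1.0, Vd=-60.0, EDV=120.0)


@pytest.fixture(scope="session")
def scenario_pair(heart_high, heart_low):
    hi = ScenarioConfig("high", heart_high, PreloadPolicy("match_SV", TARGET_SV))
    lo = ScenarioConfig("low", heart_low, PreloadPolicy("match_SV", TARGET_SV))
    return hi, lo


@pytest.fixture(scope="session")
def sim_high(fixture_tree, heart_high):
    from cvwaves import run_simulation

    return run_simulation(heart_high, fixture_tree, SolverConfig())


@pytest.fixture(scope="session")
def paired_experiment(scenario_pair, fixture_tree):
    hi, lo = scenario_pair
    return run_contractility_experiment(hi, lo, fixture_tree, SolverConfig())


@pytest.fixture(scope="session")
def sensitivity_results(scenario_pair, fixture_tree):
    hi, lo = scenario_pair
    return sensitivity_suite(hi, lo, fixture_tree, SolverConfig())
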