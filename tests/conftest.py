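import pytest
from hypothesis import HealthCheck, settings

from psp_econ import (
    build_transition_matrix,
    paper_base_case,
    propagate,
    scenario_costs,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    return paper_base_case()


@pytest.fixture(scope="session")
def matrix_no_psp(bundle):
    return build_transition_matrix(bundle.hazards_no_psp)


@pytest.fixture(scope="session")
def matrix_psp(bundle):
    return build_transition_matrix(bundle.hazards_psp)


@pytest.fixture(scope="session")
def base_results(bundle, matrix_no_psp, matrix_psp):
    """ScenarioResult for both arms of the base case."""
    out = {}
    for arm, matrix in (("no_psp", matrix_no_psp), ("psp", matrix_psp)):
        series = propagate(matrix, bundle.cohort)
        out[arm] = scenario_costs(
            series, bundle.costs_for_scenario(psp=arm == "psp"), bundle.cohort
        )
    return out
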