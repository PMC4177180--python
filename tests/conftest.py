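import pytest
from hypothesis import HealthCheck, settings

from envme import model as M
from envme import solver, toycell

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_doc():
    return toycell.generate()


@pytest.fixture(scope="session")
def toy_model(toy_doc):
    m = M.load_model(toy_doc)
    M.expand(m)
    return m


@pytest.fixture(scope="session")
def toy_solution(toy_model):
    sol = solver.maximize_growth(toy_model)
    assert sol.status == "optimal"
    return sol
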