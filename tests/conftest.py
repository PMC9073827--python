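import pytest
from hypothesis import HealthCheck, settings

import cptgdm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_problem():
    return cptgdm.worked_example()


@pytest.fixture(scope="session")
def example_report(example_problem):
    return cptgdm.solve(example_problem)
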