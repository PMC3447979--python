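import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msclkit import FixtureParams, generate_pentamer

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

COS36 = np.cos(np.pi / 5)


@pytest.fixture(scope="session")
def closed_params():
    return FixtureParams()


@pytest.fixture(scope="session")
def closed_structure(closed_params):
    return generate_pentamer(closed_params)


@pytest.fixture(scope="session")
def open_params():
    # same tilts as the closed convention so the two differ only in ring radius
    return FixtureParams(gate_circumradius=1.5 / COS36)


@pytest.fixture(scope="session")
def open_structure(open_params):
    return generate_pentamer(open_params)
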