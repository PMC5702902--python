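import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hepaflux.fixtures import (
    make_fig1_like,
    make_linear_chain,
    make_mini_liver,
    make_parallel_paths,
)


@pytest.fixture(scope="session")
def fig1():
    return make_fig1_like()


@pytest.fixture(scope="session")
def mini_liver():
    return make_mini_liver()


@pytest.fixture(scope="session")
def chain3():
    return make_linear_chain(3)


@pytest.fixture(scope="session")
def parallel():
    return make_parallel_paths()


@pytest.fixture(scope="session")
def coarse_grid():
    return np.linspace(0.0, 24.0, 49)
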