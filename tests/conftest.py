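import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hsettings

hsettings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
hsettings.load_profile("ci")

from cardiocea import AnalysisSettings, default_parameters  # noqa: E402


@pytest.fixture(scope="session")
def params():
    """The packaged base-case parameter set."""
    return default_parameters()


@pytest.fixture()
def settings():
    return AnalysisSettings()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)


def random_stochastic_matrix(rng, absorbing=(4, 5)):
    """A random row-stochastic 6x6 matrix with absorbing death states."""
    m = rng.dirichlet(np.ones(6), size=6)
    for i in absorbing:
        m[i] = 0.0
        m[i, i] = 1.0
    return m
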