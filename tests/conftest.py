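import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from afecon.fixtures import default_bundle, load_reference_fixture


@pytest.fixture(scope="session")
def bundle():
    """The packaged decision problem (published rates + synthetic values)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return default_bundle()


@pytest.fixture(scope="session")
def fixture():
    """Full fixture bundle including budget-impact inputs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_reference_fixture()
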