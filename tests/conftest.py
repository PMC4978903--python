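import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ciliamap",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ciliamap")

from ciliamap.simulate import default_genome  # noqa: E402


@pytest.fixture(scope="session")
def genome():
    """The default synthetic genome, built once per session."""
    return default_genome(np.random.default_rng(20_160_609))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
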