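import pytest
from hypothesis import HealthCheck, settings

from gelrelease import SolverConfig, reference_configuration

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference():
    """Packaged reference assay configuration."""
    return reference_configuration()


@pytest.fixture(scope="session")
def coarse_config():
    """Reduced-resolution solver settings for fast forward solves in tests."""
    return SolverConfig(n_cells_gel=24, n_cells_media=24, dt_s=900.0)


@pytest.fixture(scope="session")
def tiny_config():
    """Minimal resolution for tests that need many forward solves."""
    return SolverConfig(n_cells_gel=8, n_cells_media=8, dt_s=3600.0)
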