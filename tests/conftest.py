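import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxymap import (
    ParameterSet,
    WorldConfig,
    build_design,
    generate_world,
    run_ensemble,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def design(params):
    return build_design(params, points_per_dim=5)


@pytest.fixture(scope="session")
def world():
    return generate_world(WorldConfig(), seed=0)


@pytest.fixture(scope="session")
def archive(design, world):
    """Full default ensemble: 125 runs x 100 columns x 3 slices."""
    return run_ensemble(design, world)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211022)
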