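import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    from equicna.simulate import SimConfig

    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def marker_map(sim_config):
    from equicna.simulate import make_marker_map

    return make_marker_map(sim_config)


@pytest.fixture(scope="session")
def small_config():
    """Downsized array for fast per-test simulations."""
    from equicna.simulate import SimConfig

    return SimConfig(
        seed=7,
        marker_counts={"5": 400, "15": 400, "25": 200, "X": 800, "Y": 80},
    )


@pytest.fixture(scope="session")
def small_marker_map(small_config):
    from equicna.simulate import make_marker_map

    return make_marker_map(small_config)


@pytest.fixture(scope="session")
def fixture_tables():
    from equicna.pipeline import table_fixtures

    return table_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
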