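import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cyclexpo import (
    ModelSpec,
    build_design,
    default_scenario,
    fit_gammar,
    make_road_network,
)
from cyclexpo.pipeline import simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def small_network():
    return make_road_network(40, seed=7)


@pytest.fixture(scope="session")
def study_small(scenario):
    """A mid-sized simulated study (8 trips x 150 min = 1,200 segments):
    large enough to fit the full model, small enough for fast tests."""
    network, tracks, segments = simulate_study(
        scenario, seed=11, n_trips=8, minutes_per_trip=150
    )
    return network, tracks, segments


@pytest.fixture(scope="session")
def fitted_noise(study_small):
    _, _, segments = study_small
    return fit_gammar(build_design(segments, ModelSpec(response="noise_db")))


@pytest.fixture(scope="session")
def fitted_no2(study_small):
    _, _, segments = study_small
    return fit_gammar(build_design(segments, ModelSpec(response="no2_ugm3")))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
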