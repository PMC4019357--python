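import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import standmap

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return standmap.load_default_registry()


@pytest.fixture(scope="session")
def small_surface():
    """25x25 landscape with a 25% nonforest biomass share."""
    grid = standmap.GridSpec(25, 25)
    return standmap.generate_biomass_surface(
        grid,
        {"sill": 2500.0, "decay": 0.01, "mean": 60.0},
        nonforest_fraction=0.3,
        seed=101,
        nonforest_biomass_share=0.25,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
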