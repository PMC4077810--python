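import numpy as np
import pytest

from floodsel import simulate


@pytest.fixture(scope="session")
def landscape():
    return simulate.generate_landscape(100, 100, pixel_size=50.0, seed=1)


@pytest.fixture(scope="session")
def state_spec():
    return simulate.MovementStateSpec.from_study()


@pytest.fixture(scope="session")
def preference_trajectory(landscape, state_spec):
    """One animal with clear floodplain preference, 2000 hourly fixes."""
    return simulate.simulate_trajectory(
        landscape,
        state_spec,
        {1: 2.0, 2: 2.5, 5: 0.6, 6: 0.5},
        n_hours=2000,
        seed=4,
    )


@pytest.fixture(scope="session")
def field_records(landscape):
    return simulate.simulate_field_records(
        landscape,
        {2008: 0.35, 2009: 0.8},
        n_herds=18,
        n_sites_per_habitat=8,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
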