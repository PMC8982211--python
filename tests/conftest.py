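import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eemviab as ev

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> ev.AcquisitionGeometry:
    return ev.AcquisitionGeometry()


@pytest.fixture(scope="session")
def mask(geometry) -> ev.ValidityMask:
    return ev.build_mask(geometry)


@pytest.fixture(scope="session")
def default_dataset() -> ev.SyntheticDataset:
    """The default 6-dose × 12-replicate experiment at seed 1."""
    return ev.simulate_dataset(ev.SyntheticConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_eem(geometry, fill=1.0, **meta) -> ev.ExcitationEmissionMatrix:
    """A constant-intensity EEM on the valid cells of a geometry."""
    grid = np.full(geometry.shape, np.nan)
    grid[ev.build_mask(geometry).grid] = fill
    return ev.ExcitationEmissionMatrix(geometry=geometry, intensities=grid, **meta)
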