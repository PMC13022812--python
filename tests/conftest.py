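import numpy as np
import pytest

from seasonsdm import GridSpec, ClimateStack, make_dataset


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(lat_min=0.0, lat_max=5.0, lon_min=0.0, lon_max=5.0, cell_size=0.5)


@pytest.fixture(scope="session")
def random_stack(small_grid):
    """A fully random 3-variable stack for lookup-oracle tests."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(3, 12, *small_grid.shape))
    return ClimateStack(small_grid, ("va", "vb", "vc"), values)


@pytest.fixture(scope="session")
def month_stack(small_grid):
    """Stack whose every cell value equals its calendar month number."""
    values = np.zeros((2, 12, *small_grid.shape))
    for m in range(12):
        values[:, m] = m + 1
    return ClimateStack(small_grid, ("va", "vb"), values)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-condition synthetic dataset (seed 0), shared read-only."""
    return make_dataset(seed=0)
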