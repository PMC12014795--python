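import numpy as np
import pytest

from histopet.volumes import GridRef, ScalarVolume


@pytest.fixture
def small_grid() -> GridRef:
    """A 2 mm isotropic grid centred on the origin (64 mm cube)."""
    return GridRef((32, 32, 32), (2.0, 2.0, 2.0), (-31.0, -31.0, -31.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_volume(grid: GridRef, values: np.ndarray) -> ScalarVolume:
    return ScalarVolume(values, grid.spacing, grid.origin)
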