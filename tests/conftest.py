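import numpy as np
import pytest

from percist.phantom import default_spec, make_phantom_pair
from percist.uncertainty import UncertaintyTable
from percist.volumes import ImageGrid, ScalarVolume


@pytest.fixture(scope="session")
def static_pair():
    """Noise-bearing phantom pair with identity transforms and unchanged lesions."""
    return make_phantom_pair(default_spec(seed=7, scenario="identity", moving=False))


@pytest.fixture(scope="session")
def moving_pair():
    """Phantom pair with random per-organ rigid/affine truth transforms."""
    return make_phantom_pair(default_spec(seed=11, scenario="pmr", moving=True))


@pytest.fixture(scope="session")
def shipped_table():
    from importlib.resources import files

    path = files("percist").joinpath("data/phantom_uncertainty_table.json")
    return UncertaintyTable.from_json(str(path))


@pytest.fixture
def unit_grid():
    return ImageGrid(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))


def uniform_volume(grid: ImageGrid, value: float, kind: str = "SUL") -> ScalarVolume:
    return ScalarVolume(grid=grid, values=np.full(grid.shape, float(value)), kind=kind)
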