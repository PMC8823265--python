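import numpy as np
import pytest

from eprredox.forward import LineshapeModel, ScanProtocol
from eprredox.geometry import golden_mean_directions
from eprredox.volume import VolumeImage


@pytest.fixture(scope="session")
def lineshape():
    return LineshapeModel()


@pytest.fixture(scope="session")
def protocol():
    """Standard scan protocol without the zero-gradient scan."""
    return ScanProtocol(includes_zero_gradient=False)


@pytest.fixture(scope="session")
def small_geometry():
    """Tiny operator geometry for fast operator-level tests."""
    return {
        "directions": golden_mean_directions(32),
        "protocol": ScanProtocol(n_field_points=96, includes_zero_gradient=False),
        "matrix": 16,
        "fov": 37.5,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def ball_volume():
    """Anti-aliased ball of radius 8 mm, well inside the 37.5 mm FOV."""
    n = 32
    v = VolumeImage(np.zeros((n, n, n)), 37.5)
    cx, cy, cz = v.coords()
    r2 = cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
    v.data[:] = np.clip((8.0**2 - r2) / (8.0**2) * 4, 0, 1)
    return v
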