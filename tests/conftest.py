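import numpy as np
import pytest

from txbodies.grid import VoxelGrid


@pytest.fixture
def iso_grid():
    """Small isotropic grid for geometry-independent tests."""
    return VoxelGrid((32, 32, 32), (0.1, 0.1, 0.1))


@pytest.fixture
def aniso_grid():
    """Confocal-like anisotropic grid (0.3 μm z steps)."""
    return VoxelGrid((24, 64, 64), (0.3, 0.1, 0.1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
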