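import numpy as np
import pytest

from somaspat.geometry import BoxRegion


@pytest.fixture
def unit_cube():
    """A (1 mm)³ box region in µm coordinates."""
    return BoxRegion((0, 0, 0), (1000, 1000, 1000))


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)


@pytest.fixture
def csr_cube_pattern(unit_cube, rng):
    from somaspat.synthetic import generate_csr
    return generate_csr(unit_cube, 120, rng=rng)


@pytest.fixture
def cube_corners():
    """Corners of the unit cube (µm)."""
    g = np.array([0.0, 1000.0])
    gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
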