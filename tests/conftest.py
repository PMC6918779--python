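import numpy as np
import pytest

from neurovertex import mesh as meshmod
from neurovertex.mechanics import MechanicalParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hex44():
    """Fresh regular 4x4 hexagonal tissue."""
    return meshmod.build_hexagonal_tissue(4, 4)


@pytest.fixture
def jittered44(rng):
    """4x4 tissue with seeded vertex jitter (generic positions)."""
    m = meshmod.build_hexagonal_tissue(4, 4)
    m.vertices += 0.04 * rng.standard_normal(m.vertices.shape)
    m.wrap()
    m.invalidate()
    return m


@pytest.fixture
def params():
    return MechanicalParams(K=1.0, Lambda=0.1, Gamma=0.04, mu=1.0, dt=0.01)


@pytest.fixture
def unit_square_mesh():
    """A single 4-gon in a large box: not a tiling, but valid for the
    per-cell geometry queries."""
    verts = np.array([[1.0, 1.0], [2.0, 1.0], [2.0, 2.0], [1.0, 2.0]])
    return meshmod.Mesh(verts, [[0, 1, 2, 3]], box=(10.0, 10.0))
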