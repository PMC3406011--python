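import numpy as np
import pytest

from lvmech.geometry import GeometryParams, build_mesh
from lvmech.fibers import build_fiber_field


@pytest.fixture(scope="session")
def default_mesh():
    """Full-resolution 60-element wall mesh."""
    return build_mesh(GeometryParams(), (6, 1, 10))


@pytest.fixture(scope="session")
def small_mesh():
    """Reduced 15-element wall mesh used by the heavier solver tests."""
    return build_mesh(GeometryParams(), (3, 1, 5))


@pytest.fixture(scope="session")
def ss_field_small(small_mesh):
    return build_fiber_field(small_mesh, "ss")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
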