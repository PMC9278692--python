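import numpy as np
import pytest

from sctkit.grid import DoseGrid, StructureMask
from sctkit.phantom import default_phantom_spec, make_phantom_ct


@pytest.fixture(scope="session")
def abdominal_phantom():
    """Default abdominal phantom, shared read-only across tests."""
    spec = default_phantom_spec(seed=7)
    vol, structs = make_phantom_ct(spec)
    return spec, vol, structs


def make_small_spec():
    """A compact custom phantom for geometry-sensitive tests."""
    from sctkit.phantom import OrganSpec, PhantomSpec

    organs = (
        OrganSpec("liver", "ellipsoid", (0, -5, 25), (30, 30, 28), 54.0, 3.0),
        OrganSpec("lungs", "ellipsoid", (30, -20, -30), (20, 24, 22), -719.0, 11.0),
        OrganSpec("heart", "sphere", (30, -10, 0), (16.0, 16.0, 16.0), 36.0, 2.0),
    )
    return PhantomSpec(
        grid_shape=(24, 40, 40),
        spacing=(5.0, 4.0, 4.0),
        body_semiaxes_mm=(70.0, 75.0),
        organs=organs,
        ptv_center_mm=(0.0, -5.0, 25.0),
        ptv_radius_mm=10.0,
        seed=3,
    )


@pytest.fixture
def small_spec():
    return make_small_spec()


@pytest.fixture
def ball_mask():
    """Sphere mask factory on a small anisotropic grid."""

    def _make(radius_vox=4.0, center=(8, 8, 8), shape=(17, 17, 17),
              spacing=(1.0, 1.0, 1.0), name="ball"):
        zz, yy, xx = np.indices(shape)
        m = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
             + (xx - center[2]) ** 2) <= radius_vox**2
        return StructureMask(name, m, spacing)

    return _make


@pytest.fixture
def uniform_dose():
    def _make(value=50.0, shape=(8, 10, 10), spacing=(2.0, 2.0, 2.0),
              prescription=50.0):
        return DoseGrid(np.full(shape, float(value)), spacing,
                        prescription_gy=prescription)

    return _make
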