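import numpy as np
import pytest

from pcmrisim.eulerian import RelaxationParams
from pcmrisim.phantoms import (
    CylinderGeometry,
    GridSpec,
    StenosisGeometry,
    VelocityField,
    poiseuille_field,
)
from pcmrisim.sequence import ScanProtocol


@pytest.fixture(scope="session")
def relax():
    return RelaxationParams(t1=1.2, t2=0.25, m0=100.0)


@pytest.fixture(scope="session")
def long_relax():
    """Effectively relaxation-free spins for pure-encoding oracles."""
    return RelaxationParams(t1=1e6, t2=1e6, m0=100.0)


@pytest.fixture
def cylinder():
    return CylinderGeometry(radius_r0=4e-3, axial_length=40e-3)


@pytest.fixture
def pipe_field(cylinder):
    """Poiseuille flow, r0 = 4 mm, vmax = 0.1 m/s, on a 24x24x8 node grid."""
    grid = GridSpec.centered([12e-3, 12e-3, 40e-3], [24, 24, 8])
    return poiseuille_field(cylinder, 0.1, grid)


@pytest.fixture
def stenosis():
    return StenosisGeometry(reference_radius_rhat0=7.3e-3, characteristic_length_L=14.6e-3)


def make_plug_field(speed, extent=(16e-3, 16e-3, 40e-3), shape=(12, 12, 8), axis=2):
    """Uniform flow filling the whole box (every node is lumen)."""
    grid = GridSpec.centered(list(extent), list(shape))
    comps = [np.zeros(shape), np.zeros(shape), np.zeros(shape)]
    comps[axis] = np.full(shape, float(speed))
    return VelocityField(
        grid, *comps, lumen_mask=np.ones(shape, dtype=bool)
    )


def make_static_field(extent=(16e-3, 16e-3, 16e-3), shape=(8, 8, 8)):
    grid = GridSpec.centered(list(extent), list(shape))
    z = np.zeros(shape)
    return VelocityField(grid, z, z.copy(), z.copy(), np.ones(shape, dtype=bool))


@pytest.fixture
def small_protocol():
    """8x8 matrix scan used by fast end-to-end checks."""
    return ScanProtocol(
        tr=5e-3,
        te=4e-3,
        matrix=(8, 8),
        fov=(16e-3, 16e-3),
        slice_thickness=10e-3,
        flip_angle=np.deg2rad(4.0),
        venc=0.12,
    )
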