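import numpy as np
import pytest

from fibroquant import AcquisitionGeometry


@pytest.fixture
def iso_geom_16():
    return AcquisitionGeometry(pixel_size_xy=1.0, z_step=1.0, shape=(16, 16, 16))


@pytest.fixture
def aniso_geom():
    """3:1 axial anisotropy, as in typical confocal z-stacks."""
    return AcquisitionGeometry(pixel_size_xy=1.0, z_step=3.0, shape=(8, 16, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_geom(shape, px=1.0, zs=None):
    return AcquisitionGeometry(pixel_size_xy=px, z_step=zs if zs is not None else px, shape=shape)


@pytest.fixture
def geom_factory():
    return make_geom
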