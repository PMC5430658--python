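import numpy as np
import pytest

from erythrotomo.optics_forward import OpticalConfig
from erythrotomo.synthetic_cell import DiscocyteSpec, make_discocyte


@pytest.fixture(scope="session")
def sphere_spec():
    """A 2 μm sphere: c2 = c4 = 0, c0 = 2R degenerates the profile."""
    return DiscocyteSpec(R=2.0, c0=4.0, c2=0.0, c4=0.0, hb_true=100.0 / 3.0)


@pytest.fixture(scope="session")
def discocyte_spec():
    """The default biconcave cell scaled to the healthy mean volume."""
    return DiscocyteSpec(hb_true=33.4).scaled_to_volume(90.5)


@pytest.fixture(scope="session")
def optical_cfg():
    """Desk-scale acquisition: 128² detector, 100 nm pixels, 60 angles."""
    return OpticalConfig(detector_dims=(128, 128), n_angles=60)


@pytest.fixture(scope="session")
def sphere_volume(sphere_spec, optical_cfg):
    vol, truth = make_discocyte(
        sphere_spec, optical_cfg.pixel_size_sample, (128, 128, 128),
        n_m=optical_cfg.n_m)
    return vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
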