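import numpy as np
import pytest

from dynapet.phantom import (build_frame_schedule, default_schedule_blocks)
from dynapet.projection import (ProjectionGeometry, PSFConfig, TOFConfig,
                                build_system_operator)


@pytest.fixture(scope="session")
def protocol_schedule():
    """The clinical 53-frame / 40-min dynamic framing."""
    return build_frame_schedule(default_schedule_blocks())


def _disc_mu(n, voxel=2.0, radius=12.0, mu=0.096):
    X, Y = np.meshgrid(voxel * (np.arange(n) - (n - 1) / 2),
                       voxel * (np.arange(n) - (n - 1) / 2))
    return np.where(X**2 + Y**2 <= radius**2, mu, 0.0)


@pytest.fixture(scope="session")
def op16():
    """Plain 16x16 operator with attenuation, 24 angles."""
    return build_system_operator(_disc_mu(16), 2.0, ProjectionGeometry(n_angles=24))


@pytest.fixture(scope="session")
def op16_full():
    """16x16 operator with attenuation, TOF and PSF."""
    return build_system_operator(_disc_mu(16), 2.0, ProjectionGeometry(n_angles=24),
                                 TOFConfig(n_bins=7, bin_width_mm=12.0,
                                           kernel_fwhm_mm=30.0),
                                 PSFConfig(fwhm_mm=4.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
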