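"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

from f2f import OpticalConfig, make_bead_dataset, make_pict_fov
from f2f.registration import AffineMap


@pytest.fixture(scope="session")
def optical():
    return OpticalConfig()


@pytest.fixture(scope="session")
def optical_small():
    return OpticalConfig(image_shape=(256, 256))


@pytest.fixture(scope="session")
def distortion():
    """A mild affine distortion: 0.1% scaling plus sub-pixel translation."""
    return AffineMap.from_arrays(1.001 * np.eye(2), np.array([0.5, -0.3]))


@pytest.fixture(scope="session")
def bead_data(optical_small, distortion):
    """12 noisy bead FOVs with a known distortion and 0.2 nm loc noise."""
    return make_bead_dataset(optical_small, n_fov=12, distortion=distortion,
                             loc_noise_nm=0.2, seed=42)


@pytest.fixture(scope="session")
def cell_scene(optical):
    """One noisy 10-cell field with 20 nm pairs and 7 nm per-channel noise."""
    return make_pict_fov(optical, n_cells=10, pairs_per_cell=2,
                         true_sep_nm=20.0, loc_noise_nm=7.0, seed=11)


@pytest.fixture(scope="session")
def clean_cell_scene(optical):
    """A noise-free field: no camera noise, no localization jitter."""
    return make_pict_fov(optical, n_cells=8, pairs_per_cell=2,
                         true_sep_nm=20.0, loc_noise_nm=0.0, seed=3,
                         noise=False)
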