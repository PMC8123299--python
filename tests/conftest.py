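import numpy as np
import pytest

from pnpcyto.compensation import CompensationModel, default_mixing_matrix
from pnpcyto.config import OpticsConfig


@pytest.fixture(scope="session")
def mixing() -> CompensationModel:
    return CompensationModel.from_matrix(default_mixing_matrix())


@pytest.fixture
def small_optics() -> OpticsConfig:
    """Test-scale acquisition: 9-slice stack over a 256 px frame."""
    return OpticsConfig(image_width_px=256, image_height_px=256, z_slices=9)


@pytest.fixture
def noise_free_optics() -> OpticsConfig:
    """Deterministic rendering: no camera noise, no interior texture."""
    return OpticsConfig(
        image_width_px=256,
        image_height_px=256,
        z_slices=9,
        read_noise_sd=0.0,
        shot_noise=False,
        speckle_sigma=0.0,
        fluor_blur_px=0.0,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20210425)
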