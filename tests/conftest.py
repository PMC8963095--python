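import numpy as np
import pytest

from fissnet.grids import BinaryMask3D, IntensityVolume
from fissnet.phantom import PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bias-free phantom with well-separated intensities."""
    params = PhantomParams(grid_shape=(48, 48, 48), ellipsoid_semi_axes=(19, 16, 13),
                           n_fissures=3, noise_sigma=0.0, bias_field_amplitude=0.0,
                           seed=7)
    return generate_phantom(params)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with the default corruption settings."""
    return generate_phantom(PhantomParams(seed=11))


def volume_from(arr) -> IntensityVolume:
    return IntensityVolume(np.asarray(arr, dtype=float))


def mask_from(arr) -> BinaryMask3D:
    return BinaryMask3D(np.asarray(arr))
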