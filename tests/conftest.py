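import numpy as np
import pytest
from hypothesis import settings

import holokit as hk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def laser_setup() -> hk.OpticalSetup:
    """Reference 405 nm laser arm."""
    return hk.LASER_SETUP


@pytest.fixture(scope="session")
def led_setup() -> hk.OpticalSetup:
    """Reference 430 nm LED arm (15 nm FWHM, 15 um pinhole)."""
    return hk.LED_SETUP


@pytest.fixture()
def smooth_field() -> hk.WaveField:
    """Band-limited 128^2 complex test field (Gaussian envelope, mild tilt)."""
    x = np.linspace(-1.0, 1.0, 128)
    g = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / 0.1) * np.exp(
        1j * 3.0 * x[None, :]
    )
    return hk.WaveField(g, 1.12e-6, 405e-9)


def small_setup(
    wavelength: float = 405e-9,
    s: float = 5.91e-3,
    n: int = 64,
    pitch: float = 1.12e-6,
    **kw,
) -> hk.OpticalSetup:
    return hk.OpticalSetup(
        wavelength=wavelength,
        source_detector_distance=30e-3,
        object_detector_distance=s,
        pixel_count=n,
        pixel_pitch=pitch,
        **kw,
    )
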