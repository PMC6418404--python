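import numpy as np
import pytest

from thermospec import (
    BandSpec,
    Spectrum,
    SyntheticConfig,
    WavenumberAxis,
    generate_study,
)
from thermospec.simulate import default_axis


@pytest.fixture(scope="session")
def axis() -> WavenumberAxis:
    """The default acquisition axis (4000-898 cm^-1, 2 cm^-1 step)."""
    return default_axis()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A miniature study: 3/3/2 images of 4 x 5 pixels."""
    return SyntheticConfig(
        group_sizes={"hypothermia": 3, "hyperthermia": 3, "normothermia": 2},
        n_rows=4,
        n_cols=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture()
def gaussian_spectrum(axis):
    """Single Gaussian band at 2920 cm^-1 (amplitude 0.5, sigma 12)."""
    w = axis.values
    return Spectrum(axis, 0.5 * np.exp(-((w - 2920.0) ** 2) / (2 * 12.0**2)))


def noiseless_config(**overrides) -> SyntheticConfig:
    """A config with every stochastic term switched off."""
    defaults = dict(
        baseline_offset_range=(0.0, 0.0),
        baseline_slope_range=(0.0, 0.0),
        baseline_quad_range=(0.0, 0.0),
        scatter_range=(1.0, 1.0),
        pixel_jitter_sd=0.0,
        noise_sd=0.0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture()
def two_band_spectrum(axis):
    """Gaussian(2850, 0.3, 10) + Gaussian(2920, 0.5, 12)."""
    w = axis.values
    a = 0.3 * np.exp(-((w - 2850.0) ** 2) / (2 * 10.0**2))
    a += 0.5 * np.exp(-((w - 2920.0) ** 2) / (2 * 12.0**2))
    return Spectrum(axis, a)


def gaussian(axis: WavenumberAxis, center: float, amplitude: float,
             sigma: float) -> Spectrum:
    w = axis.values
    return Spectrum(axis, amplitude * np.exp(-((w - center) ** 2) / (2 * sigma**2)))
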