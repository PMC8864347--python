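import numpy as np
import pytest

from ticwalk import SpectralSettings, calibrate_convention

# One fixed seed for every session-scoped fixture in the suite.
SUITE_SEED = 20260101


@pytest.fixture(scope="session")
def full_settings():
    """The study-condition settings: 0.1 s grid, 300 s, 180 angles, 64 freqs."""
    return SpectralSettings()


@pytest.fixture(scope="session")
def full_calibration(full_settings):
    return calibrate_convention(full_settings, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced orientation/frequency grids for Monte-Carlo-heavy checks."""
    return SpectralSettings(n_theta=24, n_freqs=48)


@pytest.fixture(scope="session")
def fast_calibration(fast_settings):
    return calibrate_convention(fast_settings, seed=SUITE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
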