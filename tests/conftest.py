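import warnings

import numpy as np
import pytest

from lofdetect import ChannelMatrix, default_benchmark_recording
from lofdetect.errors import LowDensityWarning


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim64():
    """One 64-channel benchmark simulation (2 flat, 2 motion, 1 aperiodic)."""
    return default_benchmark_recording(64, seed=0)


@pytest.fixture(scope="session")
def sim64_batch():
    """Ten independent 64-channel benchmark simulations."""
    return [default_benchmark_recording(64, seed=s) for s in range(10)]


@pytest.fixture
def gaussian_matrix(rng):
    """Unstructured Gaussian channels: 12 channels x 400 samples."""
    return ChannelMatrix(rng.standard_normal((12, 400)), srate=100.0)


@pytest.fixture(autouse=True)
def _silence_low_density():
    """Low-density montages are used deliberately in many tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LowDensityWarning)
        yield
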