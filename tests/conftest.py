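import numpy as np
import pytest

from epoprofile.datasets.cohort import CohortSimParams, simulate_reference_lanes
from epoprofile.gel import ProfileClassifier


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free generator settings (otherwise defaults)."""
    return CohortSimParams(lane_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_params():
    return CohortSimParams()


@pytest.fixture(scope="session")
def regions(clean_params):
    """Region map calibrated from noise-free reference lanes."""
    refs = simulate_reference_lanes(clean_params)
    return ProfileClassifier().fit(list(refs)).regions_


@pytest.fixture(scope="session")
def classifier(clean_params):
    refs = simulate_reference_lanes(clean_params)
    return ProfileClassifier().fit(list(refs))


def gaussian_signal(centers, amps, sigma=0.01, n=2001):
    """Zero-baseline sum-of-Gaussians test signal on [0, 1]."""
    x = np.linspace(0.0, 1.0, n)
    y = np.zeros_like(x)
    for c, a in zip(np.atleast_1d(centers), np.atleast_1d(amps)):
        y += a * np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
    return x, y
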