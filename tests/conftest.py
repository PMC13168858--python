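import numpy as np
import pytest

from ocumet.synthetic import TraceParams, simulate_trace


@pytest.fixture
def clean_params():
    """Noise-free simulation parameters (events only)."""
    return TraceParams(
        rng_seed=7, open_fissure_sd=0.0, pupil_noise_sd=0.0, centroid_noise_sd=0.0
    )


@pytest.fixture
def clean_trace(clean_params):
    return simulate_trace(clean_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(24, 24), p=0.3):
    return rng.random(shape) < p


def random_blob(rng, shape=(48, 48), radius_range=(4, 10)):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = rng.uniform(*radius_range)
    cy = rng.uniform(r, h - r)
    cx = rng.uniform(r, w - r)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
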