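import numpy as np
import pytest

from slimphys.synthetic import SlimfieldSimConfig, simulate_image_stack
from slimphys.tracking import TrackingParams


@pytest.fixture
def default_params():
    return TrackingParams()


@pytest.fixture(scope="session")
def noiseless_single_complex():
    """One immobile pentamer, fully matured, no bleaching, no noise."""
    cfg = SlimfieldSimConfig(
        unit_size=5,
        multiple_weights={1: 1.0},
        maturation_prob=1.0,
        brightness=56.0,
        bleach_prob=0.0,
        n_complexes=1,
        diffusion_coeff=0.0,
        frame_count=3,
        image_shape=(48, 48),
        roi=(12, 12, 36, 36),
        background_rate=0.0,
        read_noise_sd=0.0,
        shot_noise=False,
        seed=11,
    )
    stack, mask, truth = simulate_image_stack(cfg)
    return cfg, stack, mask, truth


def gaussian_spot_image(
    shape, center, sigma=1.5, amplitude=50.0, background=0.0
):
    """Analytic Gaussian spot sampled at pixel centers (test oracle input)."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    img = background + amplitude * np.exp(
        -((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / (2 * sigma**2)
    )
    return img
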