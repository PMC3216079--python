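import numpy as np
import pytest

from myodamage import SimulationParams, generate_slice_image


@pytest.fixture
def small_params():
    """Small but realistic slice parameters for pixel-level brute-force checks."""

    def make(**overrides):
        defaults = dict(width=80, height=60, true_fraction=0.4, noise_sd=0.0, seed=7)
        defaults.update(overrides)
        return SimulationParams(**defaults)

    return make


@pytest.fixture
def noisy_fixture():
    """A default-size slice with moderate color noise."""
    return generate_slice_image(SimulationParams(true_fraction=0.35, noise_sd=8.0, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
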