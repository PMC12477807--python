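import numpy as np
import pytest

from punctakit import ImageStack, SimParams, simulate_stack


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_sim():
    """A small clean-ish simulated stack with ground truth."""
    params = SimParams(
        width=96, height=96, depth=10, n_spots=12, amplitude=800.0,
        amplitude_rel_var=0.1, background=200.0, noise_sd=10.0, seed=7,
    )
    return simulate_stack(params)


@pytest.fixture()
def noisy_sim():
    """A moderately noisy simulated stack (benchmark-like conditions)."""
    params = SimParams(
        width=160, height=160, depth=12, n_spots=40, seed=11,
    )
    return simulate_stack(params)


def constant_stack(value=100.0, shape=(4, 32, 32)):
    return ImageStack(np.full(shape, value))
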