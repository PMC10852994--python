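import numpy as np
import pytest

from conjcr import (
    ConditionModel,
    GridSpec,
    NoiseSpec,
    SignalSpec,
    make_signal,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    return GridSpec((40, 40))


@pytest.fixture
def circle_signals(small_grid):
    """Two overlapping smoothed circle signals scaled for threshold 2."""
    spec = SignalSpec("circle", magnitude=3.0, separation=8.0, smoothing_fwhm=3.0, radius=12.0)
    return [make_signal(spec, small_grid, i) for i in range(2)]


@pytest.fixture
def noise_spec():
    return NoiseSpec(fwhm=3.0)


def intercept_model(responses):
    n = responses.shape[0]
    return ConditionModel(responses, np.ones((n, 1)), np.ones(1))


@pytest.fixture
def toy_models(circle_signals, noise_spec, rng):
    """Two intercept-only condition models on noisy circle data (n = 40)."""
    from conjcr import generate_noise

    n = 40
    noise = generate_noise(n, 2, circle_signals[0].grid, noise_spec, rng)
    return [intercept_model(sig.values[None] + noise[i]) for i, sig in enumerate(circle_signals)]
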