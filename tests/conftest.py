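import numpy as np
import pytest

from msinrf import ModelParams, StimulusSequence


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_params():
    """Default constants on a coarser pixel grid, so kernels fit 32-px images."""
    return ModelParams(deg_per_px=0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n_frames=12, size=32, deg_per_px=0.02):
    return StimulusSequence(
        rng.random((n_frames, size, size)), fps=120.0, deg_per_px=deg_per_px
    )


@pytest.fixture()
def small_sequence(rng):
    return random_sequence(rng)
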