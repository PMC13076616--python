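import numpy as np
import pytest

from emdevo.stimuli import Arena


@pytest.fixture
def small_arena():
    """A coarse 400 µm arena that keeps rendering cheap in unit tests."""
    return Arena(width=400.0, height=400.0, pixel_size=10.0, dt=5.0)


@pytest.fixture
def fine_arena():
    """Finer grid for overlap-accuracy checks."""
    return Arena(width=400.0, height=400.0, pixel_size=5.0, dt=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
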