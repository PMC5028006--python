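import numpy as np
import pytest

from neurocascade.core import Mask, PointProcessMovie, VoltageMovie


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_movie(rng):
    """Generic 200-frame 12x10 movie with positive baseline."""
    data = 1.0 + 0.1 * rng.normal(size=(200, 12, 10))
    return VoltageMovie(data, frame_rate=50.0)


@pytest.fixture
def full_mask():
    return Mask.full(12, 10)


def make_pp(events, frame_rate=50.0, **kw):
    return PointProcessMovie(np.asarray(events, dtype=bool), frame_rate, **kw)
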