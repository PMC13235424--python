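import numpy as np
import pytest
from hypothesis import settings

from chromatrace.regions import Frame, make_rect_roi

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frames(colors, fps=1.0):
    """Uniform-color 8x8 frames from a (n, 3) array of RGB triples."""
    colors = np.asarray(colors, dtype=float)
    return [
        Frame(pixels=np.broadcast_to(c, (8, 8, 3)).copy(), t=i / fps, index=i)
        for i, c in enumerate(colors)
    ]


@pytest.fixture
def full_roi():
    return make_rect_roi(0, 0, 8, 8, (8, 8), name="full")
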