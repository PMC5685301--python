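import numpy as np
import pytest

from zfquant import ImageStack, TwoChannelStack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_pair(red: np.ndarray, green: np.ndarray, pixel_size: float = 1.0) -> TwoChannelStack:
    """Wrap raw 2D/3D uint8 arrays as a TwoChannelStack."""
    red = np.asarray(red, dtype=np.uint8)
    green = np.asarray(green, dtype=np.uint8)
    if red.ndim == 2:
        red, green = red[None], green[None]
    return TwoChannelStack(
        red=ImageStack(red, 8, pixel_size, 1.0, "SYT2"),
        green=ImageStack(green, 8, pixel_size, 1.0, "AChR"),
    )
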