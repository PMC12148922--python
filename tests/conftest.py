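import numpy as np
import pytest

from swemuscle.elastogram import ColorScale


@pytest.fixture(scope="session")
def scale() -> ColorScale:
    return ColorScale.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_overlay_frame(
    shape=(60, 80),
    region=(10, 40, 20, 70),
    swv=5.0,
    scale: ColorScale | None = None,
    grey=60,
):
    """A single synthetic RGB frame: grey background with a coloured overlay
    rectangle encoding a constant velocity. Built independently of the
    phantom generator so detection/decoding tests do not depend on it."""
    scale = scale or ColorScale.default()
    frame = np.full(shape + (3,), grey, dtype=np.uint8)
    r0, r1, c0, c1 = region
    color = scale.encode(np.full((r1 - r0, c1 - c0), float(swv)))
    frame[r0:r1, c0:c1] = color
    return frame
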