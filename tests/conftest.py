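import numpy as np
import pytest

from stdifftcv.io_sequence import FrameSequence, FrameTriplet, ImageFrame


@pytest.fixture
def disk_image():
    """Two-valued 64x64 disk (value 200 on 20); the painted pixels are truth."""
    yy, xx = np.mgrid[0:64, 0:64]
    inside = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
    return np.where(inside, 200.0, 20.0), inside


@pytest.fixture
def enclosing_circle_phi():
    """Clipped signed-distance circle of radius 22 enclosing the disk."""
    yy, xx = np.mgrid[0:64, 0:64]
    return np.clip(22.0 - np.hypot(yy - 32, xx - 32), -1.0, 1.0)


def random_triplet(seed: int, shape=(64, 64), lo=0.0, hi=255.0) -> FrameTriplet:
    rng = np.random.default_rng(seed)
    return FrameTriplet(
        *[ImageFrame(rng.uniform(lo, hi, shape), frame_index=i) for i in range(3)]
    )


def random_sequence(seed: int, n=6, shape=(64, 64), lo=0.0, hi=4095.0) -> FrameSequence:
    rng = np.random.default_rng(seed)
    return FrameSequence(frames=tuple(
        ImageFrame(rng.uniform(lo, hi, shape), frame_index=i) for i in range(n)
    ))
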