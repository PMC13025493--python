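import numpy as np
import pytest

from musclequant.ensemble import BinaryMask, ProbabilityMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260213)


@pytest.fixture
def square_mask():
    """64x64 mask with a centred 20x20 muscle square, 1 mm spacing."""
    grid = np.zeros((64, 64), dtype=np.uint8)
    grid[22:42, 22:42] = 1
    return BinaryMask(grid=grid, pixel_spacing=(1.0, 1.0))


def random_members(rng, k=4, shape=(8, 8), spacing=(1.0, 1.0)):
    return [
        ProbabilityMap(grid=rng.random(shape), pixel_spacing=spacing, provenance=f"m{i}")
        for i in range(k)
    ]


@pytest.fixture
def member_factory(rng):
    def make(k=4, shape=(8, 8), spacing=(1.0, 1.0)):
        return random_members(rng, k, shape, spacing)

    return make
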