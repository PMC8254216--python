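import numpy as np
import pytest

from epiproj import ArrayStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def stack_from_planes(planes, **calib):
    """Single-channel stack from a list of 2D planes."""
    return ArrayStack(np.stack(planes)[None], **calib)


@pytest.fixture
def checkerboard_stack():
    """8 all-zero planes except z=5, which holds a checkerboard of amplitude 100."""
    planes = [np.zeros((16, 16)) for _ in range(8)]
    cb = np.indices((16, 16)).sum(axis=0) % 2 * 100.0
    planes[5] = cb
    return stack_from_planes(planes)
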