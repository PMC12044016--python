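import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from atquant.segmentation import SegmentedStack
from atquant.stack_io import ImageStack, VoxelGeometry


@pytest.fixture
def geometry():
    return VoxelGeometry(dx=0.1, dy=0.1, dz=0.070)


def make_stack(voxels, geometry=VoxelGeometry(), channel="SYP"):
    """Build an ImageStack without the out-of-protocol section-count warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return ImageStack(np.asarray(voxels, dtype=np.float64), geometry, channel)


def make_seg(mask, geometry=VoxelGeometry(), channel="SYP"):
    return SegmentedStack(np.asarray(mask, dtype=bool), geometry, channel_name=channel)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
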