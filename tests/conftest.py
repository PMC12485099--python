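import numpy as np
import pytest

from ecmolung.mask_ops import segment_by_threshold
from ecmolung.roi_extraction import build_registry
from ecmolung.synthetic_data import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """A 64^3 mixed-aeration phantom with its ground-truth lung mask."""
    spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size_mm=(3.0, 3.0, 3.0), seed=42)
    vol, mask = generate_phantom(spec)
    return spec, vol, mask


@pytest.fixture(scope="session")
def segmented(phantom):
    _, vol, _ = phantom
    return vol, segment_by_threshold(vol)


@pytest.fixture(scope="session")
def registry(segmented):
    vol, lung = segmented
    return vol, lung, build_registry(vol, lung)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
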