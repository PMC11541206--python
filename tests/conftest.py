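import numpy as np
import pytest

from exmqc.nanocolumn import ClusterROI


def make_roi(mask, intensities, voxel_size_nm=(10.0, 10.0, 10.0), origin=(0, 0, 0)):
    """ClusterROI from raw arrays, peak at the intensity argmax inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    inten = np.where(mask, np.asarray(intensities, dtype=float), 0.0)
    masked = np.where(mask, inten, -np.inf)
    pk_local = np.unravel_index(np.argmax(masked), masked.shape)
    peak = tuple(int(o + p) for o, p in zip(origin, pk_local))
    return ClusterROI(mask, inten, tuple(origin), tuple(voxel_size_nm), peak)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def blob_roi(rng):
    """Connected random-intensity ROI inside a 10x11x12 box."""
    mask = rng.random((10, 11, 12)) < 0.45
    mask[5, 5, 6] = True
    inten = rng.random((10, 11, 12)) + 0.1
    return make_roi(mask, inten, voxel_size_nm=(30.0, 10.0, 10.0))
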