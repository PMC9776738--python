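import numpy as np
import pytest
from skimage import draw

from priorgrow.localize import Contour, trace_outer_boundary


def make_region(mask: np.ndarray, spacing_mm: float = 1.0) -> Contour:
    """Wrap a binary mask as a Contour fixture."""
    return Contour(trace_outer_boundary(mask), mask.astype(bool), spacing_mm)


@pytest.fixture
def disk_contour():
    """Filled disk, radius 40 px, centered at (60, 60) on a 130x130 grid."""
    mask = np.zeros((130, 130), dtype=bool)
    rr, cc = draw.disk((60, 60), 40, shape=mask.shape)
    mask[rr, cc] = True
    return make_region(mask)


@pytest.fixture
def dumbbell_contour():
    """Two disks joined by a thin bridge; four sector centroids fall in the gap."""
    mask = np.zeros((120, 120), dtype=bool)
    for col in (30, 90):
        rr, cc = draw.disk((60, col), 16, shape=mask.shape)
        mask[rr, cc] = True
    mask[58:63, 30:90] = True
    return make_region(mask)
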