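import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import measure


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_disk():
    """Boolean digital disk: pixels whose centers lie within radius of center."""

    def _make(shape, center, radius):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2

    return _make


@pytest.fixture
def render_disks(make_disk):
    """Render dark disks on a bright background as an 8-bit frame."""

    def _render(shape, disks, background=0.9, contrast=0.8):
        img = np.full(shape, background)
        for cy, cx, r in disks:
            img[make_disk(shape, (cy, cx), r)] = background - contrast
        return (img * 255).round().astype(np.uint8)

    return _render


@pytest.fixture
def make_blob():
    """Random connected blob within a 30x30 canvas (dilated random walk)."""

    def _make(seed, size=30, steps=40):
        rng = np.random.default_rng(seed)
        m = np.zeros((size, size), bool)
        y = x = size // 2
        for _ in range(steps):
            m[y, x] = True
            y = int(np.clip(y + rng.integers(-1, 2), 1, size - 2))
            x = int(np.clip(x + rng.integers(-1, 2), 1, size - 2))
        m = ndi.binary_dilation(m, np.ones((3, 3), bool))
        lab = measure.label(m, connectivity=2)
        areas = np.bincount(lab.ravel())
        areas[0] = 0
        return lab == areas.argmax()

    return _make
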