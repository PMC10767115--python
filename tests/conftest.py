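import numpy as np
import pytest

from emalign.fields import DisplacementField
from emalign.preprocess import SectionImage, normalize_nonzero
from emalign.synthstack import gen_smooth_field, gen_texture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def texture128():
    """Normalized cell-boundary-like texture, 128x128."""
    tex = gen_texture(3, 128)
    return normalize_nonzero(SectionImage(tex)).pixels


@pytest.fixture(scope="session")
def smooth_field64():
    """Smooth band-limited field, amplitude 2 px on a 64 grid."""
    return gen_smooth_field(7, 2.0, 24.0, 64)


def brute_force_bilinear(arr, y, x):
    """Reference bilinear sample; points outside the grid evaluate to 0."""
    H, W = arr.shape
    if not (0 <= y <= H - 1 and 0 <= x <= W - 1):
        return 0.0
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    total = 0.0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            v = arr[yy, xx] if 0 <= yy < H and 0 <= xx < W else 0.0
            total += wy * wx * v
    return total


@pytest.fixture
def bilinear_oracle():
    return brute_force_bilinear


@pytest.fixture
def windowed_sinusoid_field():
    """Smooth 2 px sinusoidal field that vanishes at the grid boundary."""

    def make(n=32, amplitude=2.0):
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        win = np.sin(np.pi * rr / (n - 1)) * np.sin(np.pi * cc / (n - 1))
        u = np.stack(
            [
                amplitude * np.sin(2 * np.pi * rr / n) * win,
                amplitude * np.cos(2 * np.pi * cc / n) * win,
            ],
            axis=-1,
        )
        return DisplacementField(u.astype(np.float32))

    return make
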