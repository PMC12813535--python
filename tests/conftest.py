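import numpy as np
import pytest

from cytoseg.ellipse import RotatedEllipse
from cytoseg.synthgen import small_cell_config, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Four 64x64 synthetic images with 1-2 cells each, exact ground truth."""
    return generate_dataset(small_cell_config(64, seed=11), 4)


def render_ellipse_mask(ellipse: RotatedEllipse, shape=(128, 128)) -> np.ndarray:
    """Brute-force point-in-ellipse rasterisation used as an independent
    oracle (every pixel centre tested against the implicit equation)."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    th = np.deg2rad(ellipse.theta)
    dx = cc - ellipse.xc
    dy = rr - ellipse.yc
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / ellipse.a) ** 2 + (v / ellipse.b) ** 2 <= 1.0
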