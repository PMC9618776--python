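import math

import numpy as np
import pytest
from skimage.draw import disk, ellipse


def make_circle(radius_px: int, pad: int = 15) -> np.ndarray:
    size = 2 * radius_px + 2 * pad
    m = np.zeros((size, size), dtype=bool)
    rr, cc = disk((size // 2, size // 2), radius_px)
    m[rr, cc] = True
    return m


def make_square(side_px: int, pad: int = 10) -> np.ndarray:
    size = side_px + 2 * pad
    m = np.zeros((size, size), dtype=bool)
    m[pad : pad + side_px, pad : pad + side_px] = True
    return m


def make_ellipse(a_px: float, b_px: float, angle: float = 0.0, pad: int = 20) -> np.ndarray:
    size = int(2 * max(a_px, b_px)) + 2 * pad
    m = np.zeros((size, size), dtype=bool)
    rr, cc = ellipse(size // 2, size // 2, a_px, b_px, rotation=angle)
    m[rr, cc] = True
    return m


def ramanujan_circularity(a: float, b: float) -> float:
    """Independent analytic oracle: 4*pi*(pi*a*b)/p^2, Ramanujan perimeter."""
    p = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    return 4 * math.pi * (math.pi * a * b) / p**2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
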