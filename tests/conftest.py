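import math

import numpy as np
import pytest

from cellfoam.geometry import EllipseModel, elliptical_radius
from cellfoam.image import ImageFrame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def circle_points():
    t = np.linspace(0, 2 * math.pi, 32, endpoint=False)
    return np.stack([50 + 10 * np.cos(t), 50 + 10 * np.sin(t)], axis=1)


def ellipse_points(cx, cy, a, b, theta, n=64):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    ex, ey = a * np.cos(t), b * np.sin(t)
    x = cx + ex * math.cos(theta) - ey * math.sin(theta)
    y = cy + ex * math.sin(theta) + ey * math.cos(theta)
    return np.stack([x, y], axis=1)


def radius_map(shape, ellipse: EllipseModel) -> np.ndarray:
    """Per-pixel elliptical radius factor, for building ring/mask images."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    return elliptical_radius(pts, ellipse).reshape(shape)


@pytest.fixture
def uniform_frame():
    return ImageFrame(np.ones((96, 96)), pixel_size=0.11)
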