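import numpy as np
import pytest


def random_convex_mask(rng: np.random.Generator, size: int = 160) -> np.ndarray:
    """Rotated ellipse mask with semi-axes in [20, 50] -- convex by construction."""
    a = rng.uniform(20, 50)
    b = rng.uniform(20, 50)
    phi = rng.uniform(0, np.pi)
    cx = rng.uniform(60, size - 60)
    cy = rng.uniform(60, size - 60)
    ys, xs = np.mgrid[0:size, 0:size]
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1


def random_convex_rays(rng: np.random.Generator, n_rays: int = 36) -> np.ndarray:
    """Ray vector of a rotated ellipse (a convex star shape about its center)."""
    a, b = rng.uniform(20, 50), rng.uniform(20, 50)
    phi = rng.uniform(0, np.pi)
    theta = np.arange(n_rays) * 2 * np.pi / n_rays
    return a * b / np.sqrt((b * np.cos(theta - phi)) ** 2 + (a * np.sin(theta - phi)) ** 2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
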