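import numpy as np
import pytest

from musfa import PhantomSpec, SFAConfig, generate_phantom, rasterize_roi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One 128x128 banded phantom with its rasterized rectangular ROI."""
    spec = PhantomSpec(shape=(128, 128), band_freq=0.75, seed=7)
    image, roi = generate_phantom(spec)
    mask = rasterize_roi(roi, image.shape)
    return spec, image, mask


@pytest.fixture(scope="session")
def default_config():
    return SFAConfig()


def random_simple_polygon(rng, rows, cols, n_vertices=8):
    """Random simple polygon: jittered evenly spaced angles keep every
    angular gap below pi, so edges live in disjoint wedges and cannot
    cross (triangles are simple regardless)."""
    cx = rng.uniform(cols * 0.3, cols * 0.7)
    cy = rng.uniform(rows * 0.3, rows * 0.7)
    angles = (2 * np.pi / n_vertices) * (np.arange(n_vertices) + 0.9 * rng.uniform(size=n_vertices))
    max_r = min(cx, cy, cols - 1 - cx, rows - 1 - cy)
    radii = rng.uniform(0.2 * max_r, 0.98 * max_r, size=n_vertices)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return np.column_stack([xs, ys])
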