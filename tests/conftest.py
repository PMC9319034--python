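import numpy as np
import pytest

from dermccm import palette as pal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_lab_palette(colors, weights=None):
    """Hand-built CIELAB palette from working-space coordinates."""
    colors = np.asarray(colors, dtype=float)
    weights = weights or [1.0] * len(colors)
    cents = tuple(
        pal.Centroid(color=c, srgb=np.clip(c / 100.0, 0, 1), weight=w)
        for c, w in zip(colors, weights)
    )
    return pal.Palette(centroids=cents, space="lab")


@pytest.fixture
def gray_palette():
    """5 equally spaced neutral centroids, Delta-E spacing exactly 1."""
    return make_lab_palette([[float(i), 0.0, 0.0] for i in range(5)])


@pytest.fixture
def rgb_palette():
    """Well-separated palette whose sRGB renderings are self-consistent."""
    from dermccm import colorspace as cs

    srgbs = np.array(
        [[0.9, 0.2, 0.2], [0.2, 0.7, 0.3], [0.25, 0.35, 0.8],
         [0.85, 0.75, 0.3], [0.5, 0.5, 0.5]]
    )
    cents = tuple(
        pal.Centroid(color=cs.srgb_to_working(s, "lab"), srgb=s, weight=1.0)
        for s in srgbs
    )
    return pal.Palette(centroids=cents, space="lab")
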