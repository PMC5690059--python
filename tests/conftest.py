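import numpy as np
import pytest

from dwcalc import synthetic_phantoms as sp


@pytest.fixture(scope="session")
def small_disk():
    """Noiseless 12-cm, 120-HU disk on a compact grid (fast pixel-exact cases)."""
    return sp.generate(sp.disk_spec(12.0, 120.0, grid=(160, 160),
                                    pixel_spacing_mm=1.0, n_slices=3))


@pytest.fixture(scope="session")
def thorax():
    """Noiseless thorax ellipse with two air lungs, default geometry."""
    return sp.generate(sp.thorax_spec(grid=(384, 384), n_slices=3))


def brute_force_ellipse_count(grid, spacing_mm, cx, cy, ax, ay):
    """Independent pixel-center oracle: count centers inside an ellipse (cm)."""
    rows, cols = grid
    s = spacing_mm / 10.0
    y = (np.arange(rows) - (rows - 1) / 2.0) * s
    x = (np.arange(cols) - (cols - 1) / 2.0) * s
    xx, yy = np.meshgrid(x, y)
    return int((((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0).sum())
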