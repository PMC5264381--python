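import numpy as np
import pytest

from blastograde.synthgen import SynthConfig, render_embryo


@pytest.fixture(scope="session")
def config():
    return SynthConfig()


@pytest.fixture(scope="session")
def grade_fixtures(config):
    """One rendered embryo per grade, fixed seed; shared across tests."""
    return {g: render_embryo(config, g, seed=7) for g in (1, 2, 3)}


@pytest.fixture(scope="session")
def ideal_circle_image():
    """Noise-free bright ring on dark background: a perfect Hough target."""
    size = 256
    rows, cols = np.mgrid[0:size, 0:size]
    d = np.hypot(cols - 128, rows - 128)
    img = np.full((size, size), 40, dtype=np.uint8)
    img[(d >= 78) & (d <= 82)] = 220
    return img
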