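import numpy as np
import pytest

from facetwear.surface_io import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_grid(rng):
    """A small random height map (16x16, µm-scale roughness)."""
    return HeightMap(rng.normal(0.0, 0.8, size=(16, 16)), dx=0.5, dy=0.5)


def cosine_surface(n_per_period=512, n_rows=32, amplitude=1.0, dx=1.0):
    """Full-period cosine along x: orthogonal to the mean plane, so the
    closed-form height moments hold exactly."""
    z = amplitude * np.cos(2 * np.pi * np.arange(n_per_period) / n_per_period)
    return HeightMap(np.tile(z, (n_rows, 1)), dx=dx, dy=dx)
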