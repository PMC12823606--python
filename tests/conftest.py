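import numpy as np
import pytest

from lymphspec.hypercube import Hypercube, Spectrum, make_default_grid
from lymphspec.synthetic import (
    SceneGeometry,
    background_spectral_model,
    body_spectral_model,
    simulate_hypercube,
    spectrum_values,
)


@pytest.fixture(scope="session")
def grid():
    return make_default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def body_spectrum(grid):
    """Noise-free skin-like reflectance spectrum on the default grid."""
    return Spectrum(spectrum_values(body_spectral_model(), grid), grid)


@pytest.fixture(scope="session")
def noiseless_scene(grid):
    """Small rendered scene with known ground-truth body mask, no noise."""
    rng = np.random.default_rng(0)
    geom = SceneGeometry(shape=(48, 64))
    cube, truth = simulate_hypercube(
        geom,
        body_spectral_model(noise_sd=0.0),
        background_spectral_model(noise_sd=0.0),
        rng,
        grid,
    )
    return cube, truth


def make_cube(values, grid):
    """Helper: cube from an (H, W, B) array."""
    return Hypercube(np.asarray(values, dtype=np.float32), grid)
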