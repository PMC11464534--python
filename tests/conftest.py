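import numpy as np
import pytest

from mitespec import generate_dataset, healthy_signature, make_grid
from mitespec.synthetic import SceneParams


@pytest.fixture(scope="session")
def camera_grid():
    """The 502-950 nm / 4 nm band grid (113 bands)."""
    return make_grid(502.0, 950.0, 4.0)


@pytest.fixture(scope="session")
def default_healthy(camera_grid):
    return healthy_signature(camera_grid)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced (40+40) synthetic MNSS dataset shared across unit tests."""
    return generate_dataset(40, 40, seed=11)


@pytest.fixture
def quiet_scene():
    """Scene with all randomness switched off (deterministic geometry)."""
    return SceneParams(
        ellipse_jitter=0.0, center_jitter=0.0, rotate=False, notch_radius=0.0,
        illumination_sigma=0.0, noise_sigma=0.0,
        leaf_variability=0.0, shape_jitter_nm=0.0, nir_tilt_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
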