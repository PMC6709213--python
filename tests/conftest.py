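import numpy as np
import pytest

from depthiem import iem, simulate
from depthiem.geometry import make_grid


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def grid_mirrored():
    return make_grid(mirrored=True)


@pytest.fixture(scope="session")
def basis():
    return iem.build_basis()


@pytest.fixture(scope="session")
def pixel_grid():
    return iem.DEFAULT_PIXEL_GRID


@pytest.fixture(scope="session")
def small_experiment():
    """2 subjects x 6 runs x 40 voxels at moderate noise; reused across tests."""
    cfg = simulate.SimConfig(n_subjects=2, n_runs=6, n_voxels=40,
                             noise_scale=0.5)
    return simulate.simulate_experiment(cfg, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
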