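import numpy as np
import pytest

from receptormap import FrameSchedule, make_phantom, simulate_dynamic
from receptormap.imageio import Image3D


@pytest.fixture(scope="session")
def phantom():
    """Standard 48-cube phantom at 2.5 mm with six regions."""
    return make_phantom(shape=(48, 48, 48), voxel_mm=2.5, n_regions=6, seed=11)


@pytest.fixture(scope="session")
def small_phantom():
    """32-cube phantom for registration-heavy tests."""
    return make_phantom(shape=(32, 32, 32), voxel_mm=2.5, n_regions=5, seed=7)


@pytest.fixture(scope="session")
def schedule20():
    return FrameSchedule.uniform(20, 300.0)


@pytest.fixture(scope="session")
def noiseless_dynamic(phantom, schedule20):
    return simulate_dynamic(phantom, schedule20, noise_sd_frac=0.0, seed=0)


@pytest.fixture(scope="session")
def plateau_dynamic(phantom):
    """Five frames deep on the equilibrium plateau (t >> 25 tau everywhere)."""
    schedule = FrameSchedule.uniform(5, 300.0, start_s=30000.0)
    return simulate_dynamic(phantom, schedule, noise_sd_frac=0.0, seed=0)


@pytest.fixture()
def structured_image(phantom):
    """A smooth, spatially structured volume for registration and metrics."""
    from receptormap import smooth_gaussian

    return smooth_gaussian(Image3D(phantom.c_eq_map, phantom.affine), 5.0)
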