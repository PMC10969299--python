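import numpy as np
import pytest

from physiomap import phantom as ph


@pytest.fixture(scope="session")
def small_phantom():
    """A noise-free 32-voxel-cube phantom with a mid-size tumor."""
    spec = ph.PhantomSpec(grid_shape=(32, 32, 32), tumor_radii=(5.0, 6.0, 4.5), seed=11)
    return ph.make_phantom(spec)


@pytest.fixture(scope="session")
def small_bundle():
    """A fully simulated noise-free patient on a 24-voxel cube."""
    spec = ph.PhantomSpec(grid_shape=(24, 24, 24), tumor_radii=(4.0, 5.0, 4.0), seed=7)
    return ph.simulate_patient(spec, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
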