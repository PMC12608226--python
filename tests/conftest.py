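import numpy as np
import pytest

import vibands as vb
from vibands.synthetic import default_leaf_model


@pytest.fixture(scope="session")
def grid_1nm():
    return vb.default_grid()


@pytest.fixture(scope="session")
def noiseless_set(grid_1nm):
    """10 noise-free cucumber-like samples on the full 1 nm grid."""
    return vb.generate_sample_set(n=10, preset="cucumber-like", seed=11,
                                  noise="none", grid=grid_1nm)


@pytest.fixture(scope="session")
def low_noise_set(grid_1nm):
    """The study-scale calibration set: 50 samples, low noise, fixed seed."""
    return vb.generate_sample_set(n=50, preset="cucumber-like", seed=7,
                                  noise="low", grid=grid_1nm)


@pytest.fixture(scope="session")
def smooth_spectrum(grid_1nm):
    """One denoised synthetic spectrum, for channel-model checks."""
    s = vb.generate_reflectance(vb.PigmentProfile(8.0, 1.8),
                                default_leaf_model("none"), grid_1nm)
    return vb.gaussian_smooth(s, 20.0)
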