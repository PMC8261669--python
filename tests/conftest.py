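import numpy as np
import pytest

import floodscore as fs


@pytest.fixture(scope="session")
def small_config():
    return fs.SimConfig(n_plots=40, seed=7)


@pytest.fixture(scope="session")
def small_field(small_config):
    scenes, manifest = fs.generate_field(small_config)
    return scenes, manifest


@pytest.fixture(scope="session")
def noisefree_config():
    return fs.SimConfig(n_plots=15, seed=3, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_field(noisefree_config):
    scenes, manifest = fs.generate_field(noisefree_config)
    return scenes, manifest


@pytest.fixture(scope="session")
def small_features(small_config, small_field):
    scenes, _ = small_field
    return fs.field_features(small_config, 20, scenes=scenes)


def pure_canopy_stack(shape=(20, 12), ndvi=0.5):
    """Reflectance stack that is canopy everywhere (no background)."""
    data = np.zeros(shape + (5,))
    data[:, :, 0] = 0.05   # blue
    data[:, :, 1] = 0.16   # green
    data[:, :, 2] = (1 - ndvi) * 0.25  # red
    data[:, :, 3] = 0.26   # red edge
    data[:, :, 4] = (1 + ndvi) * 0.25  # nir
    return fs.ReflectanceStack(data=data, method="unified_factor")


def pure_soil_stack(shape=(20, 12)):
    data = np.zeros(shape + (5,))
    data[:, :, :] = np.array([0.17, 0.22, 0.250, 0.28, 0.306])
    return fs.ReflectanceStack(data=data, method="unified_factor")
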