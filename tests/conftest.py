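import numpy as np
import pytest

import entropyscope as es


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def head():
    """Small helmet-like geometry: 48 radial sensors on a 11 cm cap."""
    pos, ori = es.spherical_sensor_array(48, array_radius=0.11)
    return es.HeadModel(sphere_center=np.zeros(3), sphere_radius=0.09,
                        sensor_positions=pos, sensor_orientations=ori)


@pytest.fixture(scope="session")
def sternberg():
    return es.generate_sternberg_paradigm(n_blocks=2, seed=7, sampling_rate=150.0)


@pytest.fixture(scope="session")
def rm():
    return es.generate_rm_paradigm(n_blocks=2, seed=7, sampling_rate=150.0)
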