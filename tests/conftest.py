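import numpy as np
import pytest

from dgfseg.core_io import RunConfig
from dgfseg.synthetic_data import NoseSpec, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def scene0():
    """Default carmoisine scene, seed 0."""
    return generate_scene(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def scene_nose():
    """Scene with a shaded nose block above the lip."""
    return generate_scene(SceneSpec(seed=4, nose=NoseSpec()))


@pytest.fixture(scope="session")
def noiseless_scene():
    return generate_scene(SceneSpec(seed=1, noise_sigma=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
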