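import numpy as np
import pytest
from hypothesis import settings

from conedet.data import SceneSpec, generate_scene, make_synthetic_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenes():
    """Six deterministic 128x128 synthetic scenes (three of each type)."""
    return make_synthetic_dataset(6, side=128, seed=1)


@pytest.fixture(scope="session")
def one_scene():
    return generate_scene(SceneSpec(image_side=128, n_targets=5, seed=7))
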