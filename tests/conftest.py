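import numpy as np
import pytest

from canopylai.config import BandOptics, SceneConfig
from canopylai.raster import BandStack
from canopylai.synthetic import make_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene with enough quadrats for model fitting."""
    config = SceneConfig(height_px=192, width_px=288, n_quadrats=24, seed=7)
    stack, lai, quadrats = make_scene(config)
    return config, stack, lai, quadrats


@pytest.fixture(scope="session")
def default_optics():
    return BandOptics()


@pytest.fixture()
def random_stack():
    """Factory for random reflectance stacks of any size."""

    def make(h=16, w=16, seed=0):
        rng = np.random.default_rng(seed)
        return BandStack(rng.uniform(0.02, 0.6, size=(h, w, 5)))

    return make
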