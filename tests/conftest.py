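import warnings

import numpy as np
import pytest

from mgmorph.morphometrics import featurize
from mgmorph.synthgen import SceneSpec, render_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 512 px synthetic scene with all six morphotypes and exact truth."""
    spec = SceneSpec(image_shape=(512, 512),
                     counts={"R": 4, "H": 3, "B": 3, "A": 3, "RD": 2, "HR": 2},
                     seed=7)
    image, truth = render_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def featurized_scene(small_scene):
    """The small scene with all 28 parameters computed on the truth cells."""
    import copy

    _, image, truth = small_scene
    annset = copy.deepcopy(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        featurize(annset, image)
    return image, annset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
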