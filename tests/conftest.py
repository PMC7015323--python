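import numpy as np
import pytest

from photoloc.detection import default_scene
from photoloc.spectra import Spectrum, SpectrumKind, default_grid
from photoloc.vision import default_visual_system


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def vsp():
    return default_visual_system()


@pytest.fixture(scope="session")
def scene_and_ambient():
    return default_scene()


@pytest.fixture(scope="session")
def scene(scene_and_ambient):
    return scene_and_ambient[0]


@pytest.fixture(scope="session")
def ambient(scene_and_ambient):
    return scene_and_ambient[1]


def flat(value, kind=SpectrumKind.REFLECTANCE, grid=None):
    return Spectrum.constant(value, kind, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20190509)
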