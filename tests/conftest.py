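import numpy as np
import pytest

from stereoslant.geometry import PlaneParams, ViewingGeometry, Window
from stereoslant.prefilter import build_lowpass
from stereoslant.stimulus import make_stereo_stimulus, make_texture_spec


@pytest.fixture(scope="session")
def vg() -> ViewingGeometry:
    """Standard viewing geometry: 6.5 cm interocular, 100 cm image plane,
    48 px/deg raster."""
    return ViewingGeometry()


@pytest.fixture(scope="session")
def small_window() -> Window:
    """A reduced analysis window for fast observer tests."""
    return Window(center=(0.0, 0.0), width=1.25, height=1.1)


@pytest.fixture(scope="session")
def fs16(vg):
    return build_lowpass(16.0, vg)


@pytest.fixture(scope="session")
def fs5(vg):
    return build_lowpass(5.0, vg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stim(slant=60.0, zeta=99.0, noise=0.0, seed=0, vg=None, window=None):
    spec = make_texture_spec(seed=seed)
    plane = PlaneParams(slant, 0.0, zeta)
    return make_stereo_stimulus(
        spec, plane, vg or ViewingGeometry(), noise_rms=noise, seed=seed + 1,
        window=window,
    )
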