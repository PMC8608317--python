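import numpy as np
import pytest

from hazvis.filtering import LuminanceImage
from hazvis.scene import SceneSpec, render_scene
from hazvis.vision import VisionParams, build_csf

# desk-scale scene configuration: same 25.6 deg field of view as the
# full-resolution default, at a quarter of the linear resolution
SMALL_SCENE = dict(image_size=(128, 128), ppd=5.0)
MID_SCENE = dict(image_size=(256, 256), ppd=10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def normal_vision():
    return VisionParams(acuity=0.0, contrast_sensitivity=1.95)


@pytest.fixture(scope="session")
def moderate_vision():
    return VisionParams(acuity=1.2, contrast_sensitivity=0.68)


@pytest.fixture(scope="session")
def severe_vision():
    return VisionParams(acuity=1.62, contrast_sensitivity=0.60)


@pytest.fixture(scope="session")
def normal_csf(normal_vision):
    return build_csf(normal_vision)


@pytest.fixture(scope="session")
def step_render():
    """A mid-resolution big-step-up render with strong riser contrast."""
    return render_scene(
        SceneSpec(target="big-step-up", lighting="spotlight-1", viewpoint="center", **MID_SCENE)
    )


@pytest.fixture(scope="session")
def flat_render():
    return render_scene(
        SceneSpec(target="flat", lighting="near-panel", viewpoint="center", **MID_SCENE)
    )


def make_grating(
    frequency_cpd: float,
    contrast: float,
    mean: float = 100.0,
    size: int = 128,
    ppd: float = 16.0,
) -> LuminanceImage:
    """A horizontal sinusoidal luminance grating of given Michelson contrast."""
    x = np.arange(size) / ppd  # degrees
    profile = mean * (1.0 + contrast * np.sin(2 * np.pi * frequency_cpd * x))
    return LuminanceImage(np.tile(profile, (size, 1)), ppd)
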