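import numpy as np
import pytest
from hypothesis import settings

from guvkit.synthetic import SyntheticScene, render_scene

settings.register_profile("default", derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_tube_scene():
    """A low-noise rendered tube-pulling scene with known ground truth."""
    scene = SyntheticScene(scene_kind="guv_with_tube", tube_ratio_membrane=0.4,
                           sorting_true=2.0, psf_sigma_px=1.0, noise_sd=2.0,
                           seed=7)
    image, record = render_scene(scene)
    return scene, image, record


@pytest.fixture(scope="session")
def noiseless_scene():
    """A blur-free, noise-free scene: ratios are exact by construction."""
    scene = SyntheticScene(scene_kind="guv_with_tube", tube_ratio_membrane=0.3,
                           sorting_true=1.0, psf_sigma_px=0.0, noise_sd=0.0,
                           seed=0)
    image, record = render_scene(scene)
    return scene, image, record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
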