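import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile("parseg", derandomize=True)
hypothesis.settings.load_profile("parseg")

from parseg.pixel_data import PixelDataset, build_pixel_dataset
from parseg.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def separable_scene():
    """Zero-noise scene with disjoint color supports: trivially separable."""
    spec = SceneSpec(
        height=64,
        width=64,
        n_objects=5,
        axis_range=(5, 9),
        fg_color_sd=0.0,
        bg_color_sd=0.0,
        pixel_noise_sd=0.0,
        seed=7,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    """Realistic small scene: Gaussian class colors plus pixel noise."""
    spec = SceneSpec(height=96, width=96, n_objects=8, axis_range=(7, 13), seed=21)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def noisy_dataset(noisy_scene) -> PixelDataset:
    image, truth = noisy_scene
    return build_pixel_dataset(image, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
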