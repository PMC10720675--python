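import numpy as np
import pytest

from nodemorph.synthetic import SlideSpec, generate_slide


@pytest.fixture(scope="session")
def default_slide():
    """One default synthetic slide with ground truth (3 sections)."""
    return generate_slide(SlideSpec(seed=7))


@pytest.fixture(scope="session")
def small_slide():
    """A small single-section slide for fast tests."""
    spec = SlideSpec(n_sections=1, slide_shape=(340, 340),
                     section_radius_px=(100, 140), gc_count_per_section=(2, 6),
                     seed=11)
    return generate_slide(spec)


class ConstantModel:
    """Inference stub: predicts a constant probability everywhere."""

    def __init__(self, p=0.8):
        self.p = p

    def predict(self, x):
        return np.full(x.shape[:1] + x.shape[2:], self.p)


class MeanBrightnessModel:
    """Fully convolutional stub: probability = mean RGB brightness per pixel.

    Purely pointwise, hence free of padding sensitivity — stitched and
    whole-image predictions must agree exactly.
    """

    def predict(self, x):
        return x.mean(axis=1)


@pytest.fixture
def constant_model():
    return ConstantModel(0.8)


@pytest.fixture
def brightness_model():
    return MeanBrightnessModel()
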