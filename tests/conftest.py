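import numpy as np
import pytest

from groomdet.preprocess import PreprocessConfig
from groomdet.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_scene():
    """Small arena for quick rendering in unit tests."""
    return SceneConfig(arena_side=128, body_axes=(12.0, 7.0),
                       facial_osc=(2.0, 4), body_osc=(6.0, 8), seed=7)


@pytest.fixture
def fast_preprocess():
    return PreprocessConfig(crop_side=64, out_side=32)
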