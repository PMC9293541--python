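import numpy as np
import pytest

from wbcseg import (
    ModelConfig,
    RenderedSample,
    SceneConfig,
    TrainConfig,
    generate_samples,
)
from wbcseg.preprocessing import AugmentConfig


@pytest.fixture(scope="session")
def small_scene_config() -> SceneConfig:
    """A 64-px smear world used across the fast tests."""
    return SceneConfig(
        image_size=64,
        wbc_count_range=(1, 3),
        wbc_radius_range=(6, 11),
        rbc_count_range=(6, 14),
        rbc_radius_range=(3, 5),
    )


@pytest.fixture(scope="session")
def tiny_scene_config() -> SceneConfig:
    """A 16-px world for training-loop bookkeeping tests."""
    return SceneConfig(
        image_size=16,
        wbc_count_range=(1, 1),
        wbc_radius_range=(3, 5),
        rbc_count_range=(0, 2),
        rbc_radius_range=(2, 3),
    )


@pytest.fixture(scope="session")
def tiny_samples(tiny_scene_config) -> list[RenderedSample]:
    return generate_samples(24, tiny_scene_config, seed=11)


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    return ModelConfig(input_side=16, width_multiplier=1 / 28, dropout_rate=0.1)


@pytest.fixture()
def tiny_train_config(tiny_model_config) -> TrainConfig:
    return TrainConfig(
        epochs=2,
        batch_size=4,
        seed=5,
        model=tiny_model_config,
        augment=AugmentConfig(enabled=False),
    )


def random_mask_pairs(n_pairs: int, side: int, seed: int):
    """Random binary mask pairs, including blob-like and degenerate cases."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        if i % 10 == 0:
            a = np.zeros((side, side), dtype=np.uint8)
        else:
            a = (rng.random((side, side)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        if i % 10 == 1:
            b = a.copy()
        else:
            b = (rng.random((side, side)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        pairs.append((a, b))
    return pairs
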