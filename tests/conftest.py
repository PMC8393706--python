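import numpy as np
import pytest

from histocaps import ModelSpec, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1485)


@pytest.fixture
def random_image(rng):
    """A 32x32 random RGB image in [0, 1]."""
    return rng.uniform(0.0, 1.0, (32, 32, 3))


@pytest.fixture
def cast_image(rng):
    """A red-blue-dominant image (green mean depressed), like an H&E tile."""
    img = rng.uniform(0.3, 0.7, (48, 48, 3))
    img[..., 0] += 0.2
    img[..., 2] += 0.2
    return np.clip(img, 0.0, 1.0)


@pytest.fixture(scope="session")
def tiny_model_spec():
    """A shrunken architecture for fast forward/backward tests."""
    return ModelSpec(
        input_shape=(16, 16, 3),
        conv_channels=8,
        n_block_layers=2,
        primary_capsules_clb=4,
        primary_capsules_sclb=2,
        primary_capsule_dim=4,
        class_capsules=5,
        class_capsule_dim=6,
        routing_iterations=3,
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A small generated dataset shared across tests (8 per class, 5 classes)."""
    spec = SyntheticSpec(n_per_class=8, image_size=(32, 32), seed=7)
    images, labels, names = generate_dataset(spec)
    return spec, images, labels, names
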