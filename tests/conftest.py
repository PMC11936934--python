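import numpy as np
import pytest

from neurostage.data import PhantomConfig, generate_phantom_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Low-contrast 8x8 RGB image for oracle comparisons."""
    return rng.uniform(0.3, 0.7, size=(8, 8, 3))


@pytest.fixture(scope="session")
def small_phantom_tree(tmp_path_factory):
    """5 classes x 12 small phantoms, generated once per session."""
    root = tmp_path_factory.mktemp("phantoms")
    cfg = PhantomConfig(n_classes=5, per_class=12, image_size=(32, 32), seed=7)
    manifest = generate_phantom_dataset(cfg, root)
    return root, cfg, manifest
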