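import numpy as np
import pytest

from lca.augment import build_default_space


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_space():
    return build_default_space()


@pytest.fixture(scope="session")
def lesion_image():
    """One deterministic dermoscopy-like test image."""
    from lca.synthetic import SyntheticSpec, generate_dataset

    spec = SyntheticSpec(class_counts={"A": 1}, image_size=(96, 96), seed=7)
    images, _ = generate_dataset(spec)
    return images[0]
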