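import numpy as np
import pytest

from gazefusion import (GazeFusionClassifier, PhantomConfig,
                        generate_phantom_dataset, stack_dataset)


@pytest.fixture(scope="session")
def small_phantom():
    """Small seeded phantom dataset shared by read-only tests."""
    cfg = PhantomConfig(n_samples=24, image_size=32, seed=7,
                        lesion_radius_range=(4.0, 8.0))
    return generate_phantom_dataset(cfg)


@pytest.fixture(scope="session")
def small_arrays(small_phantom):
    return stack_dataset(small_phantom)


@pytest.fixture(scope="session")
def tiny_fitted(small_arrays):
    """A quickly fitted tiny2 fusion model for contract tests (not accuracy)."""
    X, y = small_arrays
    clf = GazeFusionClassifier(backbone="tiny2", epochs=2, learning_rate=1e-3,
                               batch_size=8, random_state=0)
    return clf.fit(X, y)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
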