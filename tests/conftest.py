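import numpy as np
import pytest

import akscreen as ak


@pytest.fixture(scope="session")
def tiny_dataset() -> ak.LabeledImageSet:
    """12 small, well-separated synthetic lesion images (6 per class)."""
    return ak.generate_dataset(
        ak.SynthConfig(n_per_class=6, image_size=32, separation=1.0, seed=3)
    )


@pytest.fixture(scope="session")
def easy_dataset() -> ak.LabeledImageSet:
    """The well-separated 200-per-class study dataset (separation 1, seed 1)."""
    return ak.generate_dataset(
        ak.SynthConfig(n_per_class=200, image_size=64, separation=1.0, seed=1)
    )


@pytest.fixture(scope="session")
def easy_standardized(easy_dataset):
    X = ak.ImageStandardizer().transform(easy_dataset.images)
    return X, easy_dataset.labels


@pytest.fixture(scope="session")
def trained_cnn_easy(easy_standardized) -> ak.ShallowCNNClassifier:
    """Shallow CNN trained for the default 30 epochs on the easy task."""
    X, y = easy_standardized
    model = ak.ShallowCNNClassifier(epochs=30, init_seed=0, shuffle_seed=0)
    return model.fit(X, y)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rgb(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    return rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
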