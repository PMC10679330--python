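import numpy as np
import pytest

from msgaug import (ClassifierConfig, SyntheticDatasetConfig,
                    generate_dataset, train_classifier)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 texture classes, 16x16, 40 images per class."""
    return generate_dataset(SyntheticDatasetConfig(
        n_classes=3, per_class_count=40, resolution=16, seed=11))


@pytest.fixture(scope="session")
def tiny_classifier(tiny_dataset):
    """A quickly trained 3-class scorer over the tiny dataset."""
    config = ClassifierConfig(n_classes=3, epochs=4, batch_size=32,
                              lr_initial=0.01, momentum=0.9, seed=3)
    model, log = train_classifier(tiny_dataset, None, config)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
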