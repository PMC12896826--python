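import numpy as np
import pytest

from herdnet.classifier import SResNetClassifier
from herdnet.synth import GeneratorConfig, make_pipeline_datasets


@pytest.fixture(scope="session")
def small_splits():
    """Small standardized train/val/test splits from the default generator."""
    return make_pipeline_datasets(
        GeneratorConfig(n_total=600, seed=2), seed=2, val_fraction=0.2
    )


@pytest.fixture(scope="session")
def tiny_clf(small_splits):
    """A briefly trained classifier shared by structural tests."""
    train, _, _ = small_splits
    return SResNetClassifier(epochs=3, random_state=0).fit(train.X, train.y)


@pytest.fixture(scope="session")
def untrained_clf(small_splits):
    """Randomly initialized classifier (epochs=0) for structure-only tests."""
    train, _, _ = small_splits
    return SResNetClassifier(epochs=0, random_state=0).fit(train.X, train.y)
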