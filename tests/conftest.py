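"""Shared fixtures.

The trained fixture model is expensive (~1-2 min on one CPU) so it is built
once per session and shared by the end-to-end and acceptance tests.
"""

import numpy as np
import pytest

from crmap.model_core import DenseHead, FeatureMapStack
from crmap.synthetic import (
    GeneratorConfig,
    generate_dataset,
    train_fixture_model,
)

#: pinned training seed for the default fixture model (see ledger): the
#: directional CRM-vs-CAM comparisons are empirical, model-dependent claims,
#: so the fixture is trained with a fixed seed for deterministic assertions.
FIXTURE_SEED = 1
FIXTURE_EPOCHS = 40


@pytest.fixture
def toy_fm() -> FeatureMapStack:
    """2x2x2 worked example: f_1 = [[1,0],[0,1]], f_2 = [[0,2],[0,0]]."""
    f1 = np.array([[1.0, 0.0], [0.0, 1.0]])
    f2 = np.array([[0.0, 2.0], [0.0, 0.0]])
    return FeatureMapStack(np.stack([f1, f2], axis=-1), image_id="toy")


@pytest.fixture
def toy_head() -> DenseHead:
    """Identity-like weights, zero biases."""
    return DenseHead(np.eye(2), np.zeros(2))


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small dataset for cheap contract tests (not for accuracy claims)."""
    cfg = GeneratorConfig(
        images_per_class={"train": 3, "val": 1, "test": 2}, master_seed=7
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_fixture(default_dataset):
    """(adapter, metrics) for the default fixture training run."""
    return train_fixture_model(
        default_dataset, seed=FIXTURE_SEED, epochs=FIXTURE_EPOCHS
    )
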