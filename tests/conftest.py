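import os

# single-threaded numerics: bit-exact reproducibility of seeded training runs
for var in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from ageaug import (DinoConfig, PhantomSpec, ThresholdSpec, TrainConfig,
                    ViTConfig, build_backbone, generate_dataset)


@pytest.fixture(scope="session")
def toy_vit_config():
    return ViTConfig(image_size=32, patch_size=8, n_heads=6, depth=2, embed_dim=48)


@pytest.fixture(scope="session")
def toy_backbone(toy_vit_config):
    return build_backbone(toy_vit_config, seed=0)


@pytest.fixture(scope="session")
def calc_dataset():
    """60 train / 21 val / 18 test calcification phantoms (3 classes)."""
    spec = PhantomSpec(task="calcification_patch")
    return generate_dataset(33, spec, (0.6, 0.2, 0.2), seed=11)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small dataset for fast training-loop unit tests."""
    spec = PhantomSpec(task="calcification_patch")
    return generate_dataset(6, spec, (0.6, 0.2, 0.2), seed=3)


@pytest.fixture(scope="session")
def screening_config():
    """Frozen-backbone full-batch screening configuration (head/P selection)."""
    return TrainConfig(epochs=100, batch_size=60, learning_rate=1e-2,
                       weight_decay=0.01, patience=80, screening_epochs=80,
                       freeze_backbone=True)


@pytest.fixture(scope="session")
def finetune_config():
    """Desk-scale full fine-tuning configuration."""
    return TrainConfig(epochs=60, batch_size=8, learning_rate=1e-4,
                       weight_decay=1e-4, patience=10, n_repeats=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
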