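"""Shared fixtures.

The expensive trained-model fixtures are session-scoped: the hybrid and the
CNN-only ablation baseline are trained once, under identical conditions, on
the standard 150-phantom dataset, and reused by every test that needs a
trained network.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridsnn import (
    AugmentConfig,
    HybridSNNClassifier,
    PhantomParams,
    ablation_compare,
    stratified_kfold,
    synth_phantoms,
)

SEED = 20240917


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def phantom_dataset():
    """150 low-noise phantoms, 50 per class — the standard desk-scale fixture."""
    return synth_phantoms(PhantomParams(seed=SEED), n_per_class=50)


@pytest.fixture(scope="session")
def phantom_split(phantom_dataset):
    folds = stratified_kfold(phantom_dataset, k=5, seed=SEED)
    return folds.split(0)


@pytest.fixture(scope="session")
def ablation_result(phantom_dataset, phantom_split):
    """Hybrid and CNN-only models trained under identical conditions."""
    train_idx, val_idx = phantom_split
    return ablation_compare(
        phantom_dataset, train_idx, val_idx, seed=SEED,
        augment=AugmentConfig(),
    )


@pytest.fixture(scope="session")
def trained_hybrid(ablation_result) -> HybridSNNClassifier:
    return ablation_result["hybrid"]["model"]


@pytest.fixture(scope="session")
def hippo_phantoms():
    """Phantom family whose only discriminating structure is the
    hippocampal blob (ventricles and cortex tied across classes)."""
    params = PhantomParams(
        image_size=64,
        ventricle_radius={"AD": 10.0, "CI": 10.0, "CN": 10.0},
        cortex_thickness={"AD": 6.0, "CI": 6.0, "CN": 6.0},
        hippocampus_radius={"AD": 6.0, "CI": 10.0, "CN": 14.0},
        pixel_noise_sd=0.02,
        seed=SEED,
    )
    return synth_phantoms(params, n_per_class=40)


@pytest.fixture(scope="session")
def hippo_model(hippo_phantoms):
    """Hybrid trained to discriminate hippocampal-blob size only."""
    folds = stratified_kfold(hippo_phantoms, k=5, seed=SEED)
    train_idx, val_idx = folds.split(0)
    clf = HybridSNNClassifier(input_shape=(64, 64, 3), random_state=SEED,
                              augment=AugmentConfig())
    clf.fit(hippo_phantoms.images[train_idx],
            hippo_phantoms.labels[train_idx],
            hippo_phantoms.images[val_idx],
            hippo_phantoms.labels[val_idx])
    return clf, val_idx


@pytest.fixture(scope="session")
def small_estimator_params():
    """A fast configuration for tests that only exercise mechanics."""
    return dict(
        input_shape=(32, 32, 3),
        conv_channels=(4, 8),
        feature_dim=16,
        hidden_dim=8,
        max_epochs=2,
        batch_size=16,
    )


@pytest.fixture(scope="session")
def small_phantoms():
    return synth_phantoms(
        PhantomParams(image_size=32, seed=SEED), n_per_class=12
    )
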