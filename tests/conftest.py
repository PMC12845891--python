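"""Shared fixtures: synthetic datasets and the trained reference model."""

from __future__ import annotations

import numpy as np
import pytest

from ecgseg import ModelConfig, UNet1d
from ecgseg.synthetic import RhythmSpec, default_training_mix, generate_dataset
from ecgseg.training import TrainConfig, train

# conditions of the end-to-end synthetic experiment
TRAIN_SEED, VAL_SEED, TEST_SEED = 101, 202, 303
N_TRAIN, N_VAL, N_TEST = 400, 30, 50


@pytest.fixture(scope="session")
def small_dataset():
    """30 annotated 20-s records with mixed ectopy (fast unit-test fuel)."""
    data, manifest = generate_dataset(
        30, default_training_mix(), duration_s=20.0, fs=125.0, seed=7
    )
    return data, manifest


@pytest.fixture(scope="session")
def trained_model():
    """Small model trained at the full experiment scale.

    400 training records (~10% PVC, ~10% PAC), 30 validation records for
    early stopping, 10 epochs. Returns (model, held-out test records).
    """
    mix = default_training_mix()
    train_data, _ = generate_dataset(N_TRAIN, mix, 20.0, 125.0, seed=TRAIN_SEED)
    val_data, _ = generate_dataset(N_VAL, mix, 20.0, 125.0, seed=VAL_SEED)
    test_data, _ = generate_dataset(N_TEST, mix, 20.0, 125.0, seed=TEST_SEED)
    model = UNet1d(ModelConfig(blocks_per_stage=(1, 1, 1, 1)), seed=0)
    config = TrainConfig(epochs=10, batch_size=4, seed=0, early_stop_patience=4)
    model, history = train(model, train_data, val_data, config)
    return model, test_data, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
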