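"""Shared fixtures.

The expensive classifier (trained on synthetic windows) is built once per
session and shared by the detection-level and acceptance tests; unit tests
use a small architecture instead.
"""

from __future__ import annotations

import numpy as np
import pytest

try:  # single-threaded BLAS keeps float32 training bit-reproducible
    from threadpoolctl import threadpool_limits
    _limiter = threadpool_limits(1)  # held for the whole session
except ImportError:  # pragma: no cover
    pass

from minievents.nn import (ConvBlockSpec, ModelSpec, TrainConfig,
                           build_classifier, train_classifier)
from minievents.synth import SyntheticEventSpec, make_training_set

TRAIN_SEED = 7

#: hyperparameters of the session classifier; the learning rate is raised
#: above the published default so the run converges inside the test budget
TRAIN_CFG = TrainConfig(learning_rate=7e-4, max_epochs=22,
                        early_stop_patience=5, seed=TRAIN_SEED)


def small_spec(window_len: int = 60) -> ModelSpec:
    """A scaled-down architecture for fast unit tests (same layer types)."""
    return ModelSpec(
        window_len=window_len,
        conv_blocks=(ConvBlockSpec(8, 9, 3), ConvBlockSpec(12, 7, 2),
                     ConvBlockSpec(16, 5, 2), ConvBlockSpec(20, 3, None)),
        lstm_units=8, dense_units=16)


@pytest.fixture(scope="session")
def train_spec() -> SyntheticEventSpec:
    return SyntheticEventSpec()


@pytest.fixture(scope="session")
def training_set(train_spec):
    return make_training_set(train_spec, 2000, 2000, noise_sd=1.0,
                             noise_model="filtered",
                             amplitude_range=(2.0, 16.0), seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_model(training_set):
    """Classifier trained once on ~4000 synthetic windows (few minutes)."""
    model = build_classifier(seed=TRAIN_SEED)
    return train_classifier(model, training_set, TRAIN_CFG)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
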