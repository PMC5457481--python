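"""Shared fixtures.

The trained-network fixture runs the full synthetic-scene pipeline once
per session at a reduced scale (fewer scenes and epochs than the
library defaults) so every training-dependent test shares one model.
"""

import pytest

from binodepth.analysis import make_rds_test_set, make_training_data
from binodepth.bnn import TrainConfig, init_bnn, train


@pytest.fixture(scope="session")
def trained_bnn():
    """A 2-way network trained on synthetic naturalistic stereo patches."""
    train_set, val_set, _ = make_training_data(n_scenes=300, seed=0)
    model = init_bnn(init_noise=0.1, seed=100)
    model, history = train(
        model,
        train_set,
        val_set,
        TrainConfig(learning_rate=0.004, max_epochs=90, seed=0),
    )
    return model


@pytest.fixture(scope="session")
def crds_test_set():
    return make_rds_test_set(n=3000, seed=11)


@pytest.fixture(scope="session")
def ards_test_set():
    return make_rds_test_set(n=3000, correlated=False, seed=12)
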