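import numpy as np
import pytest

import lasenet as ln
from lasenet.datasets import default_prior, sample_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_session(model_id, n_trials=80, seed=0):
    """One simulated agent with prior-drawn parameters."""
    rng = np.random.default_rng(seed)
    params = sample_parameters(default_prior(model_id), 1, rng)[0]
    task = ln.default_task(model_id, n_trials)
    session, latents = ln.simulate(model_id, params, task, rng)
    return params, session, latents


@pytest.fixture(scope="session")
def tiny_trained_4prl():
    """A small estimator genuinely trained on 4P-RL data (shared across
    network tests to keep the suite fast)."""
    from lasenet import models as cm
    from lasenet.datasets import build_dataset
    from lasenet.network import (
        NetworkConfig, TrainingConfig, build_network, train_estimator,
    )
    task = cm.default_task(ln.FOURP_RL, 60)
    ds = build_dataset(ln.FOURP_RL, default_prior(ln.FOURP_RL), 60, task,
                       np.random.default_rng(11))
    net = build_network(NetworkConfig(gru_units=16, head_cont=1), 2, seed=3)
    tcfg = TrainingConfig(learning_rate=3e-3, batch_size=16, max_epochs=30,
                          early_stop_patience=29, seed=5)
    return train_estimator(net, ds, tcfg), ds
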