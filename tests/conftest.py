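"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from diaxic import deep_rep, synth


@pytest.fixture(scope="session")
def tiny_exp():
    """Small, fully present, high-SNR synthetic experiment for unit tests."""
    cfg = synth.SynthConfig(
        n_precursors=60, n_cycles_total=60, n_windows=16, seed=5
    )
    return synth.generate_experiment(cfg)


@pytest.fixture(scope="session")
def small_model():
    """A compact trained representation model shared by pipeline-level tests.

    Hidden sizes (32, 16) keep the LSTM forward pass cheap while preserving
    the architecture (two LSTM layers + FC 16/1); the training set comes from
    the generator's default conditions.
    """
    cfg = synth.SynthConfig(seed=7)
    X, y, groups = synth.generate_rsm_training_set(cfg, 2000, seed=7)
    model = deep_rep.build_model(
        X.shape[1], X.shape[2], seed=1, hidden_sizes=(32, 16)
    )
    deep_rep.train(model, X, y, epochs=8, seed=1, groups=groups)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
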