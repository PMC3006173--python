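"""Shared fixtures.

The expensive artifacts (a full strong-effect session and its
preprocessed band tensors) are built once per test session and reused by
the classifier, evaluation and acceptance tests.
"""

import numpy as np
import pytest

import lfpdecode as ld


@pytest.fixture(scope="session")
def strong_session():
    """Default strong-effect synthetic session (32 ch, 40 trials/class)."""
    cfg = ld.SimConfig(seed=11)
    T, truth = ld.simulate_session(cfg)
    return cfg, T, truth


@pytest.fixture(scope="session")
def strong_banded(strong_session):
    """Delta + gamma band tensors of the strong session."""
    _, T, _ = strong_session
    return ld.preprocess_bands(T, ld.informative_bands())


@pytest.fixture(scope="session")
def small_session():
    """Cheap session for structural tests (16 ch, 15 trials/class)."""
    cfg = ld.SimConfig(seed=21, n_channels=16, n_trials_per_class=15)
    T, truth = ld.simulate_session(cfg)
    return cfg, T, truth


@pytest.fixture(scope="session")
def small_banded(small_session):
    _, T, _ = small_session
    return ld.preprocess_bands(T, ld.informative_bands())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
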