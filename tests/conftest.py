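import numpy as np
import pytest

import enoprune as ep
from enoprune.ensemble import VoteMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """Two-class sensor dataset small enough for fast pipeline tests."""
    cfg = ep.SimConfig(n_samples_per_class=60, n_channels=4, n_timesteps=30,
                       class_separation=0.8, noise_sd=0.8, drift_sd=0.05,
                       seed=3)
    samples = ep.generate_dataset(cfg)
    X, y = ep.signals_to_matrix(samples)
    return samples, X, y


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated low-noise dataset: any sane pipeline scores high."""
    cfg = ep.SimConfig(n_samples_per_class=40, n_channels=4, n_timesteps=30,
                       class_separation=3.0, noise_sd=0.1, drift_sd=0.0,
                       seed=5)
    samples = ep.generate_dataset(cfg)
    X, y = ep.signals_to_matrix(samples)
    return samples, X, y


@pytest.fixture()
def vote_fixture():
    votes, labels = ep.generate_vote_matrix(
        ep.VoteSimConfig(n_samples=40, n_classifiers=11,
                         per_classifier_accuracy=0.7,
                         inter_classifier_correlation=0.3, seed=7))
    return VoteMatrix(votes, labels)
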