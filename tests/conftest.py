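"""Shared fixtures: tiny synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cmcsel.coherence import DEFAULT_BANDS, FeatureMatrix, build_feature_matrix
from cmcsel.preprocessing import preprocess_recording
from cmcsel.synthetic import Coupling, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """A 2-subject, M=2 x Q=2 benchmark small enough for unit tests."""
    return SynthConfig(
        n_subjects=2,
        trials_per_class=(6, 3),
        eeg_labels=("C3", "Cz"),
        emg_labels=("AD", "FDI"),
        couplings=(Coupling("AD", "C3", "alpha", 1, 2.5, echo_channel=None),),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_dataset):
    recs, _ = tiny_dataset
    return preprocess_recording(recs[0])


@pytest.fixture(scope="session")
def tiny_features(tiny_bundle):
    return build_feature_matrix(tiny_bundle)


def make_feature_matrix(values, labels, subject_ids, M=1, Q=None) -> FeatureMatrix:
    """Wrap a raw array as a FeatureMatrix with a fabricated K=11 layout.

    The column count must be a multiple of 11; Q is inferred from it.
    """
    values = np.asarray(values, dtype=float)
    K = DEFAULT_BANDS.K
    if Q is None:
        assert values.shape[1] % (M * K) == 0
        Q = values.shape[1] // (M * K)
    eeg = tuple(f"E{i}" for i in range(Q))
    emg = tuple(f"M{i}" for i in range(M))
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels),
        subject_ids=np.asarray(subject_ids),
        M=M,
        Q=Q,
        scheme=DEFAULT_BANDS,
        emg_labels=emg,
        eeg_labels=eeg,
    )


@pytest.fixture(scope="session")
def planted_matrix():
    """A directly constructed feature matrix with 5 planted columns of 176.

    Noise columns share the class means; planted columns separate the two
    classes by about five noise standard deviations.
    """
    rng = np.random.default_rng(11)
    n_per_class, p = 60, 176
    planted = [3, 40, 77, 114, 151]
    X = np.clip(rng.normal(0.3, 0.05, size=(2 * n_per_class, p)), 0, 1)
    y = np.repeat([1, 2], n_per_class)
    for c in planted:
        X[y == 1, c] = np.clip(rng.normal(0.65, 0.05, size=n_per_class), 0, 1)
    subjects = np.tile(["SA", "SB"], n_per_class)
    return make_feature_matrix(X, y, subjects, M=2), planted
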