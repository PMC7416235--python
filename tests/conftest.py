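from __future__ import annotations

import numpy as np
import pytest

from circleemd import (
    CircularSignal,
    FeatureSpec,
    build_features,
    circle_emd,
    decompose_dataset,
)
from circleemd.preprocess import run_preprocessing
from circleemd.synthetic import EmulatedStudySpec, make_emulated_study


@pytest.fixture(scope="session")
def two_tone_256():
    """8-cycle + 2-cycle circular signal with its clean components."""
    i = np.arange(256)
    fast = np.cos(2 * np.pi * 8 * i / 256)
    slow = np.cos(2 * np.pi * 2 * i / 256)
    return CircularSignal(fast + slow), fast, slow


@pytest.fixture(scope="session")
def two_tone_decomposition(two_tone_256):
    signal, _, _ = two_tone_256
    return circle_emd(signal)


@pytest.fixture(scope="session")
def default_dataset():
    """The emulated study pushed through the full preprocessing flow."""
    study, patterns = make_emulated_study(EmulatedStudySpec(seed=1))
    dataset, tvals = run_preprocessing(study)
    return dataset, tvals, patterns


@pytest.fixture(scope="session")
def default_decompositions(default_dataset):
    dataset, _, _ = default_dataset
    return decompose_dataset(dataset)


@pytest.fixture(scope="session")
def all_imf_features(default_dataset, default_decompositions):
    dataset, _, _ = default_dataset
    return build_features(dataset, FeatureSpec(mode="all_imfs"), default_decompositions)
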