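from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import safvision as sv
from safvision.features import FEATURE_NAMES
from safvision.pipeline import extract_feature_table, feature_matrix

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_corpus() -> sv.synth.Corpus:
    """A 7x6 corpus (no spectral frames) shared across the session."""
    cfg = sv.CorpusConfig(images_per_class=6, include_spectral=False, seed=11)
    return sv.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    """(features table, X, y) extracted from the small corpus."""
    table = extract_feature_table(small_corpus)
    X, y = feature_matrix(table, FEATURE_NAMES)
    return table, X, y


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
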