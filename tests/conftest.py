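from __future__ import annotations

import numpy as np
import pytest

from ehgkit.features import FeatureConfig, extract_cohort_features
from ehgkit.preprocess import preprocess_recording
from ehgkit.simulate import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_920)


@pytest.fixture(scope="session")
def small_cohort():
    """12-recording cohort with short recordings for fast structural tests."""
    cfg = SyntheticCohortConfig(
        n_per_class=(4, 8), duration_s=360.0, class_effect=1.0, seed=5, horizon=7
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    processed = [preprocess_recording(r) for r in small_cohort.recordings]
    feats = extract_cohort_features(processed, FeatureConfig())
    return feats.reset_index(drop=True)
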