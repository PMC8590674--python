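import numpy as np
import pytest

import ripsleep as rs


@pytest.fixture(scope="session")
def small_cohort():
    """Six short synthetic studies with AHIs spanning the severity range."""
    base = rs.SyntheticStudyConfig(n_epochs=120, seed=0)
    return rs.generate_cohort(6, (0, 40), base, seed=123)


@pytest.fixture(scope="session")
def small_record(small_cohort):
    return small_cohort[0][0]


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Per-recording (normalized FeatureMatrix, hypnogram) pairs."""
    return [
        (rs.robust_normalize(rs.extract_epoch_features(rec)), hyp)
        for rec, hyp, _ in small_cohort
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
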