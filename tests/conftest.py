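import numpy as np
import pytest

from moveprofiles import cohort, features


@pytest.fixture(scope="session")
def small_cohort():
    """n=150 default-archetype cohort with epoch data (shared, read-only)."""
    cfg = cohort.CohortConfig(n_participants=150, seed=42)
    days, truth = cohort.simulate_cohort(cfg)
    return cfg, days, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, days, truth = small_cohort
    return features.extract_features(days), truth


@pytest.fixture(scope="session")
def cohort1000():
    """Default-condition cohort (n=1000, 7 days) with its feature table."""
    cfg = cohort.CohortConfig(n_participants=1000, seed=20260930 % (2**31 - 1))
    days, truth = cohort.simulate_cohort(cfg)
    feats = features.extract_features(days)
    return feats, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
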