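import numpy as np
import pytest

import gaitsubpop as g


@pytest.fixture(scope="session")
def small_study() -> g.WaveformStudy:
    """A compact three-subpopulation cohort with follow-up and controls."""
    cfg = g.CohortConfig(
        n_per_subpop=(12, 12, 12),
        n_hc=14,
        n_followup_per_subpop=(6, 6, 6),
        recovery_fraction=(0.7, 0.7, 0.7),
        seed=7,
    )
    return g.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_reduced(small_study):
    """Preprocessed scores/basis/stats for the compact cohort."""
    return g.reduce_study(small_study)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
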