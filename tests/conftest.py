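from __future__ import annotations

import numpy as np
import pytest

from neosleep import SimConfig, assemble_features, simulate_cohort, simulate_recording
from neosleep.preprocess import preprocess_recording

#: Problem sizes for cohort-level tests: 8 subjects x 90 epochs (45 min) each,
#: enough epochs per state for LOSO folds while keeping the suite fast.
COHORT_EPOCHS = 90
COHORT_SUBJECTS = 8


@pytest.fixture(scope="session")
def small_recording():
    """One 40-epoch recording with all channels, fixed seed."""
    return simulate_recording(SimConfig(seed=11, duration_epochs=40))


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    return preprocess_recording(small_recording)


@pytest.fixture(scope="session")
def cohort_features_factory():
    """Factory (seed -> cohort feature matrix), cached across tests."""
    cache: dict[int, object] = {}

    def make(seed: int):
        if seed not in cache:
            cfg = SimConfig(seed=seed, duration_epochs=COHORT_EPOCHS)
            recs = simulate_cohort(cfg, n_subjects=COHORT_SUBJECTS)
            cache[seed] = assemble_features(recs)
        return cache[seed]

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
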