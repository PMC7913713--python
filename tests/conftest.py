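import numpy as np
import pytest
from hypothesis import settings

import seizedefer as sd

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 patients x 1 h, no artifacts; fast and fully deterministic."""
    cfg = sd.desk_preset(
        n_patients=3, duration_s=3600, artifact_rate=0.0, seed=42
    )
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """6 patients x 2 h with artifact bursts; used by detection-level tests."""
    cfg = sd.desk_preset(n_patients=6, duration_s=7200, seed=7)
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fs_labels(small_cohort):
    return {
        p.patient_id: sd.derive_labels(p.events, "fs", p.segments.n_segments)
        for p in small_cohort
    }


def rng(seed=0):
    return np.random.default_rng(seed)
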