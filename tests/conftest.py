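import numpy as np
import pytest

from leidakit.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 2 sessions x 1 modality, 24 ROIs, 3 planted states."""
    config = CohortConfig(
        n_subjects=4,
        n_sessions=2,
        modalities=(("SB-ASSET2", 2.0, 120),),
        n_roi=24,
        n_networks=4,
        k_true=3,
        seed=7,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def artifact_cohort():
    """Small cohort with motion-coupled artifacts injected into the BOLD signal."""
    config = CohortConfig(
        n_subjects=8,
        n_sessions=1,
        modalities=(("SB-ASSET2", 2.0, 240),),
        n_roi=24,
        n_networks=4,
        k_true=3,
        artifact_gain=1.0,
        motion_spike_rate=0.02,
        seed=5,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
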