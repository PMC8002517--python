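import numpy as np
import pytest
from hypothesis import settings

import eegident as ei

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

CHANNELS6 = tuple(f"C{i}" for i in range(6))


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects, 6 channels, 30 s, identity planted in (30, 50) Hz."""
    spec = ei.SyntheticCohortSpec(
        n_subjects=12,
        n_channels=6,
        sampling_rate=160.0,
        duration=30.0,
        identity_band=(30.0, 50.0),
        separability=1.0,
        seed=7,
        channel_labels=CHANNELS6,
    )
    return ei.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_pipeline():
    return ei.PipelineConfig(
        channel_set=CHANNELS6,
        filter_order=1,
        band=(30.0, 50.0),
        duration=30.0,
    )


@pytest.fixture(scope="session")
def small_feature_space(small_cohort, small_pipeline):
    return ei.build_feature_space(small_cohort.recordings, small_pipeline)


def ar2_series(coeffs, n, seed=0, burn=500):
    """Simulate an AR process x_t = sum a_i x_{t-i} + e_t."""
    rng = np.random.default_rng(seed)
    p = len(coeffs)
    e = rng.standard_normal(n + burn)
    x = np.zeros(n + burn)
    for t in range(p, n + burn):
        x[t] = sum(c * x[t - i - 1] for i, c in enumerate(coeffs)) + e[t]
    return x[burn:]
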