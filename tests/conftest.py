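import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_pipeline_warnings():
    """Pipeline stages warn on dropped records; tests assert on returns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def clean_recording():
    """One noise-free 10 s recording with its ground-truth fiducials."""
    import ecgid

    m = ecgid.sample_subject_morphology(1)
    rec, truth = ecgid.simulate_recording(m, seed=3)
    return m, rec, truth


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject, 4-record clean cohort shared across expensive tests."""
    import ecgid

    manifest, recs, truths = ecgid.simulate_cohort(10, 4, noise="clean", seed=5)
    return manifest, recs, truths


def rng_pairs(n, length, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield rng.standard_normal(length), rng.standard_normal(length)
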