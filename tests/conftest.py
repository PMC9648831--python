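import numpy as np
import pytest

from eegpref.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort_config() -> CohortConfig:
    """A short-segment cohort for fast unit tests (covers 0-8 s application)."""
    return CohortConfig(
        n_subjects=3,
        n_trials_per_subject=4,
        segment_span=(-2.0, 10.0),
        application_span=(0.0, 8.0),
        seed=1234,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return generate_cohort(tiny_cohort_config)


@pytest.fixture(scope="session")
def one_recording(tiny_cohort):
    return tiny_cohort[0]


def make_frames(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random positive (n, 4, 5, 5) band frames."""
    return rng.gamma(2.0, 1.0, size=(n, 4, 5, 5))
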