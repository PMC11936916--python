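import pytest
from hypothesis import settings

from pccvr import AnalysisOptions, CohortConfig, Schedule, generate_cohort

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A small default-noise cohort shared by read-only tests."""
    config = CohortConfig(n_subjects=4, n_sessions=2, seed=5,
                          schedule=Schedule.compact())
    return generate_cohort(config)


@pytest.fixture(scope="session")
def zero_noise_study():
    """Noise-free cohort: pipeline estimates must equal ground truth."""
    config = CohortConfig(n_subjects=5, n_sessions=3, seed=7,
                          schedule=Schedule.compact()).without_noise()
    return generate_cohort(config)


@pytest.fixture()
def fixed_threshold_options():
    return AnalysisOptions(meaningful_change_threshold=2.0)
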