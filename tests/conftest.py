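import pytest

from ovistereo.simulate import CohortDesign, default_cohort_params, generate_cohort


@pytest.fixture(scope="session")
def default_params():
    return default_cohort_params()


@pytest.fixture(scope="session")
def study_cohort(default_params):
    """Synthetic cohort at the study's design: three groups of ten."""
    return generate_cohort(CohortDesign(seed=1), default_params)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """Small cohort for fast pipeline/IO tests."""
    return generate_cohort(CohortDesign(seed=2, n_per_group=4), default_params)
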