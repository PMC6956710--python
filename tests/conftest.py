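import pytest

from fibrointegra import study_profile, simulate_cohort
from fibrointegra.synthetic_data import groups_from_truth

COHORT_SEED = 20260925


@pytest.fixture(scope="session")
def cohort():
    """One study-profile synthetic cohort (10 normal / 16+4+4 fibroids)."""
    ds, truth = simulate_cohort(study_profile(seed=COHORT_SEED), seed=COHORT_SEED)
    return ds, truth


@pytest.fixture(scope="session")
def cohort_groups(cohort):
    _, truth = cohort
    return groups_from_truth(truth)
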