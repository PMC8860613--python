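import pytest

from telosubmeth import SyntheticTruth, simulate_cohort


@pytest.fixture(scope="session")
def default_truth():
    return SyntheticTruth(seed=11)


@pytest.fixture(scope="session")
def cohort(default_truth):
    """One synthetic end plus observed methylomes for all six genotypes."""
    syn, profiles, truths = simulate_cohort(default_truth)
    return syn, profiles, truths


@pytest.fixture(scope="session")
def wt_profile(cohort):
    return cohort[1]["WT"]
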