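import pytest

from cdlr import CDLRParams, simulate_cohort, study_like_defaults


@pytest.fixture(scope="session")
def mean_params():
    """Published mean-dose curve parameters."""
    return CDLRParams(beta=0.0517, gamma=3.3587)


@pytest.fixture(scope="session")
def max_params():
    """Published maximum-dose curve parameters."""
    return CDLRParams(beta=0.0994, gamma=6.8876)


@pytest.fixture(scope="session")
def study_cohort():
    """One study-sized synthetic cohort (38 patients x 2 ears, mean dose)."""
    return simulate_cohort(study_like_defaults("mean", seed=7))
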