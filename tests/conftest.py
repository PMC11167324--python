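import pytest

from bpcoach.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small closed-loop cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_participants=8, weeks=8, seed=11))
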