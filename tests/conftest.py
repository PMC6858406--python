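import numpy as np
import pandas as pd
import pytest

from limbvol.cohort import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """n = 18 default-spec cohort (seed 22) with profiles; all four group
    pipelines are known to complete on it."""
    return generate_cohort(default_cohort_spec(n_subjects=18, seed=22))


@pytest.fixture(scope="session")
def demo_cohort_noprofiles():
    return generate_cohort(
        default_cohort_spec(n_subjects=18, seed=22, make_profiles=False)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
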