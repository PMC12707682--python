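import numpy as np
import pytest

from permawell import (
    default_prior,
    default_spec,
    generate_cohort,
    scale_features,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-student synthetic cohort, feature-scaled, with all labels."""
    return scale_features(generate_cohort(default_spec(n=50, seed=42)))


@pytest.fixture(scope="session")
def small_prior(small_cohort):
    return default_prior(small_cohort.schema)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
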