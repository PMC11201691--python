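import numpy as np
import pytest

from stresslab.cohort import CohortSpec, EffectSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny reduced-profile cohort shared by read-only tests."""
    spec = CohortSpec.fast(n_per_group=3, seed=11)
    return generate_cohort(spec, EffectSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
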