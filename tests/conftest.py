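import numpy as np
import pytest

from rcc_radiomics import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort shared by read-only tests: 6/3/3 at 16^3."""
    cfg = CohortConfig(
        counts={"ccRCC": 6, "pRCC": 3, "cRCC": 3}, shape=(16, 16, 16), seed=5
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
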