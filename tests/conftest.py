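import numpy as np
import pytest

from coda24 import Composition, GeneratorParams, generate_cohort

#: Published first-pivot contrasts ("behavior vs remaining") used as the
#: worked example throughout the tests: BMI in kg/m², WC in cm, in
#: canonical (sleep, SED, LPA, MVPA) order.
TABLE_BMI_BETAS = (1.34, -0.09, -0.66, -0.60)
TABLE_WC_BETAS = (1.51, 2.39, -1.76, -2.14)

#: Pre-retirement compositional mean of the reference cohort, minutes/day.
REFERENCE_MINUTES = (497.0, 584.0, 282.0, 77.0)


@pytest.fixture(scope="session")
def reference() -> Composition:
    return Composition.from_minutes(REFERENCE_MINUTES)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230523)


def random_compositions(rng: np.random.Generator, n: int) -> list[Composition]:
    """Random strictly-positive 4-part compositions (logistic-normal)."""
    z = rng.normal(0.0, 1.0, size=(n, 4))
    return [Composition(tuple(np.exp(row))) for row in z]


@pytest.fixture(scope="session")
def cohort() -> "pandas.DataFrame":
    """Mid-sized synthetic cohort with moderate noise, reused across tests."""
    return generate_cohort(GeneratorParams(n=400, seed=11, residual_sd=0.5))


@pytest.fixture(scope="session")
def noisefree_cohort() -> "pandas.DataFrame":
    """Cohort whose outcome change is an exact linear function of Δclr."""
    return generate_cohort(GeneratorParams(n=300, seed=5, residual_sd=0.0,
                                           wc_residual_sd=0.0))
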