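import numpy as np
import pytest

from maddwi.model import BValueScheme, MADParameters
from maddwi.synthetic import (
    default_scheme,
    high_grade_distribution,
    low_grade_distribution,
)


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    """The 12-b-value acquisition scheme with NEX averaging counts."""
    return default_scheme()


@pytest.fixture(scope="session")
def low_dist():
    return low_grade_distribution()


@pytest.fixture(scope="session")
def high_dist():
    return high_grade_distribution()


@pytest.fixture(scope="session")
def low_means(low_dist) -> MADParameters:
    """Low-grade group-mean parameters, fractions renormalized to sum 1."""
    return low_dist.mean_params()


def random_valid_params(rng: np.random.Generator) -> MADParameters:
    """A random parameter set from the identifiable interior of the bounds.

    Each fraction is kept >= 0.05 and the diffusivities are kept separated
    (D_h away from both its bounds, D_f well above the fixed unimpeded
    rate); at compartment collapse the model is structurally
    non-identifiable and no criterion on recovery is meaningful.
    """
    fr = rng.dirichlet([2.0, 4.0, 3.0, 2.0])
    fr = 0.05 + 0.8 * fr
    fr = fr / fr.sum()
    return MADParameters(
        D_r=rng.uniform(0.01, 0.15),
        D_h=rng.uniform(0.5, 2.5),
        D_f=rng.uniform(6.0, 60.0),
        alpha_h=rng.uniform(0.6, 1.2),
        f_r=float(fr[0]), f_h=float(fr[1]), f_ui=float(fr[2]), f_f=float(fr[3]),
    )
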