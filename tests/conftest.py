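import math

import numpy as np
import pytest

from nanorheo.basis import BSplineBasis
from nanorheo.contact import ProbeCellGeometry
from nanorheo.profiles import make_capped_sinusoid, make_triangular, random_profile


@pytest.fixture(scope="session")
def basis():
    return BSplineBasis()


@pytest.fixture(scope="session")
def geometry_thick():
    """Semi-infinite sample: no bottom-effect terms."""
    return ProbeCellGeometry(theta=math.radians(25.0), h=np.inf)


@pytest.fixture(scope="session")
def geometry_thin():
    """Thin sample, 7 um, typical pyramidal-probe half angle."""
    return ProbeCellGeometry(theta=math.radians(25.0), h=7e-6)


@pytest.fixture(scope="session")
def triangle(basis):
    """Symmetric triangle: I_max 1 um at 10 um/s, 0.1 s per branch."""
    return make_triangular(1e-6, 10e-6, 10e-6, basis)


@pytest.fixture(scope="session")
def profile_zoo(basis):
    """A mixed bag of admissible profiles for parametrized checks."""
    return [
        make_triangular(1e-6, 10e-6, 10e-6, basis),
        make_triangular(2e-6, 5e-6, 15e-6, basis),
        make_capped_sinusoid(1e-6, 0.4, basis),
        random_profile(11, basis),
        random_profile(42, basis),
        random_profile(1234, basis),
    ]
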