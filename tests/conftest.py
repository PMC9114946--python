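import numpy as np
import pytest

from tendonfit import MaterialParams, TriangularRecruitment, generate_synthetic


@pytest.fixture
def dist():
    """A general triangular recruitment distribution used throughout."""
    return TriangularRecruitment(1.04, 1.10, 1.16)


@pytest.fixture
def mat():
    return MaterialParams(7.0, 800.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def synthetic_record():
    """Noisy synthetic tensile test at the canonical generating parameters."""
    mat = MaterialParams(7.0, 800.0)
    dist = TriangularRecruitment.symmetric(1.03, 1.13)
    return generate_synthetic(mat, dist, noise_var=0.01, seed=1)


def random_triangle(rng, allow_degenerate=False):
    """Draw a valid recruitment triangle with support inside (1, 1.4)."""
    a = 1.0 + rng.uniform(0.005, 0.12)
    b = a + rng.uniform(0.01, 0.25)
    frac = rng.uniform(0.0, 1.0) if allow_degenerate else rng.uniform(0.05, 0.95)
    return TriangularRecruitment(a, a + frac * (b - a), b)
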