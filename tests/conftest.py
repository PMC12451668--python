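import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def sp_orbital_pairs():
    """Contraction data for the randomized s/p diatomic test orbitals."""
    return {
        "A": {"exponents": (0.9, 0.35), "coefficients": (0.7, 0.8)},
        "B": {"exponents": (1.2, 0.3), "coefficients": (1.0, 0.5)},
    }


def random_symmetric_eri(rng, M):
    """A random tensor with the full eightfold index symmetry."""
    B = rng.normal(size=(M, M, M, M))
    e = B + B.transpose(1, 0, 2, 3)
    e = e + e.transpose(0, 1, 3, 2)
    e = e + e.transpose(2, 3, 0, 1)
    return e
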