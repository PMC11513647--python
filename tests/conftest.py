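import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

GOLDEN_LAMBDA = (1 + np.sqrt(5)) / 2


@pytest.fixture
def golden_leslie():
    """Two-stage Leslie matrix with dominant eigenvalue (1+sqrt(5))/2.

    A = [[1, 2], [0.5, 0]] splits into survival U (the 0.5 transition) and
    reproduction F (the top row); its characteristic polynomial is
    x^2 - x - 1, so every derived quantity has a closed form.
    """
    A = np.array([[1.0, 2.0], [0.5, 0.0]])
    U = np.array([[0.0, 0.0], [0.5, 0.0]])
    F = np.array([[1.0, 2.0], [0.0, 0.0]])
    return A, U, F


def random_gated_mpm(rng: np.random.Generator, n_min=3, n_max=6):
    """A random strictly positive MPM (hence primitive and ergodic).

    U columns are scaled to survival sums in (0.2, 0.95); F is a sparse-ish
    nonnegative reproduction matrix with at least one positive column.
    """
    n = int(rng.integers(n_min, n_max + 1))
    U = rng.uniform(0.05, 1.0, size=(n, n))
    U *= rng.uniform(0.2, 0.95, size=n) / U.sum(axis=0)
    F = rng.uniform(0.0, 2.0, size=(n, n)) * (rng.random((n, n)) < 0.4)
    F[0, -1] += rng.uniform(0.5, 2.0)
    return U + F, U, F


@pytest.fixture
def make_gated_mpm():
    return random_gated_mpm


@pytest.fixture(scope="session")
def small_study():
    """A 40-species synthetic study shared by the integration tests."""
    from phylodem import make_dataset

    return make_dataset(n_species=40, seed=20250401, missing_rate=0.12)
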