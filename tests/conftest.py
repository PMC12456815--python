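import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hicwalk as hw

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study1_spec() -> hw.IdealizedSpec:
    """The five-block idealized layout (200 loci; sizes 50/30/20/90/10)."""
    return hw.IdealizedSpec(N=200, block_sizes=(50, 30, 20, 90, 10), d=0.0)


@pytest.fixture(scope="session")
def study1_spec_d() -> hw.IdealizedSpec:
    """Same layout with d = 1/(2N) = 0.0025 between-block probability."""
    return hw.IdealizedSpec(N=200, block_sizes=(50, 30, 20, 90, 10), d=0.0025)


def sinkhorn_balance(A: np.ndarray, iters: int = 20000, tol: float = 1e-13) -> np.ndarray:
    """Independent slow symmetric Sinkhorn oracle: x <- x / sqrt(x * (A x))."""
    x = np.ones(A.shape[0])
    for _ in range(iters):
        r = x * (A @ x)
        x = x / np.sqrt(r)
        if np.abs(x * (A @ x) - 1.0).max() < tol:
            break
    return (x[:, None] * A) * x[None, :]


def random_doubly_stochastic(n: int, rng: np.random.Generator) -> hw.StochasticMatrix:
    """Random symmetric doubly stochastic matrix via Sinkhorn balancing."""
    A = rng.uniform(0.2, 2.0, size=(n, n))
    A = A + A.T
    P = sinkhorn_balance(A)
    return hw.StochasticMatrix(P, tolerance=1e-10)
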