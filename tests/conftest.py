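import numpy as np
import pytest

from screenmf.data import StateMatrix, TimeGrid, WeightMatrix
from screenmf.factorization import (
    FactorizationConfig,
    FactorModel,
    make_regularizer,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state_matrix(rng, n=6, t=10, density=0.6):
    """Small random partially observed state matrix for unit tests."""
    values = rng.integers(1, 5, size=(n, t))
    mask = rng.random((n, t)) < density
    mask[:, 0] = True  # keep every row non-empty
    return StateMatrix(np.where(mask, values, 0), mask, TimeGrid(t))


@pytest.fixture
def small_matrix(rng):
    return random_state_matrix(rng)


def model_from_latent(latent, theta=2.5):
    """Wrap a fixed latent matrix as a FactorModel (V = identity)."""
    latent = np.asarray(latent, dtype=float)
    n, t = latent.shape
    return FactorModel(
        U=latent.copy(),
        V=np.eye(t),
        shifts=np.zeros(n, dtype=np.int64),
        theta=theta,
        config=FactorizationConfig(rank=t),
        regularizer=make_regularizer("difference", t),
    )
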