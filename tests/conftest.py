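import numpy as np
import pytest

from chemevol import DominanceParams, ModelParams


@pytest.fixture
def defaults() -> ModelParams:
    """Standard parameter set (N=500, theta=1, one herbivore, L=10, c=0.02)."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240905)


def dom(da, dc, L=10) -> DominanceParams:
    return DominanceParams.broadcast(da, dc, L)
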