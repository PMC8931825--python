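import numpy as np
import pytest

from ivoiseg.phantom import PhantomSpec, cpu_preset


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Very small grid for fast structural tests."""
    return cpu_preset(grid_shape=(16, 32, 32), spacing_mm=(0.8, 0.625, 0.625), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask(rng: np.random.Generator, shape=(4, 4, 4), p: float = 0.5) -> np.ndarray:
    return rng.random(shape) < p
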