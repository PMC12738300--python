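import numpy as np
import pytest

from pavgnb.synthdata import ScenarioSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """A small, clearly separated 3-class dataset (n=120, p=6)."""
    return generate_dataset(
        ScenarioSpec(n=120, p=6, K=3, spacing=3.0, rho=0.2, seed=7))


@pytest.fixture
def tiny_xy(rng):
    """Unstructured 2-class data for parameter-level checks."""
    X = rng.normal(size=(40, 5))
    y = np.array(["a", "b"] * 20)
    return X, y
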