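import numpy as np
import pytest

from multipletfit import default_registry


@pytest.fixture()
def registry():
    """A fresh registry per test so registrations cannot leak."""
    return default_registry()


@pytest.fixture()
def fine_grid():
    return np.linspace(0.0, 4.0, 8001)


def perturbed(value: float, frac: float, rng: np.random.Generator) -> float:
    return value * (1.0 + rng.uniform(-frac, frac))
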