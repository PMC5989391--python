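import numpy as np
import pytest

from methnet.containers import VariableVector


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def exact_corr_pair(n: int, r: float, seed: int = 0):
    """Two unit-sample-variance vectors with sample correlation exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = x - x.mean()
    e = e - e.mean()
    e = e - (e @ x) / (x @ x) * x  # orthogonalize
    x = x / x.std(ddof=1)
    e = e / e.std(ddof=1)
    y = r * x + np.sqrt(1.0 - r * r) * e
    return x, y


@pytest.fixture
def corr_half():
    """Pair with sample Pearson correlation exactly 0.5."""
    return exact_corr_pair(100, 0.5)


def as_vectors(named_arrays: dict) -> list[VariableVector]:
    return [VariableVector(k, v) for k, v in named_arrays.items()]
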