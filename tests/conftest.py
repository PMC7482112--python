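import numpy as np
import pytest


def random_pd(n: int, rng: np.random.Generator, ridge: float | None = None) -> np.ndarray:
    """Well-conditioned random symmetric positive-definite matrix."""
    A = rng.standard_normal((n, n))
    K = A @ A.T
    K += (ridge if ridge is not None else n) * np.eye(n)
    return (K + K.T) / 2.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
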