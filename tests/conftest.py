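import numpy as np
import pytest

from wakenet.io import Recording


def random_weight_matrix(n: int, rng, density: float = 1.0) -> np.ndarray:
    """Random symmetric weight matrix in [0, 1] with zero diagonal."""
    upper = rng.random((n, n))
    if density < 1.0:
        upper = np.where(rng.random((n, n)) < density, upper, 0.0)
    W = np.triu(upper, k=1)
    return W + W.T


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def sine_recording():
    """Two-channel recording: 10 Hz and 2 Hz unit sinusoids at 500 Hz."""
    fs = 500.0
    t = np.arange(0, 60, 1 / fs)
    data = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 2 * t)])
    return Recording(["a", "b"], fs, data)
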