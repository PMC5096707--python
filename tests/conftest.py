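import numpy as np
import pytest

from prefmode import PopulationTensor


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_tensor(rng):
    """Generic 5×4×6 random tensor."""
    return PopulationTensor.from_values(rng.standard_normal((5, 4, 6)))


def loop_unfold(values: np.ndarray, mode: str) -> np.ndarray:
    """Independent, loop-built unfolding (time-major columns) used as the
    oracle against the vectorized implementation."""
    n, c, t = values.shape
    if mode == "neuron":
        out = np.zeros((n, c * t))
        for i in range(n):
            for tt in range(t):
                for j in range(c):
                    out[i, tt * c + j] = values[i, j, tt]
    else:
        out = np.zeros((c, n * t))
        for j in range(c):
            for tt in range(t):
                for i in range(n):
                    out[j, tt * n + i] = values[i, j, tt]
    return out
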