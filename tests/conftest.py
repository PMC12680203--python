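import numpy as np
import pytest

from mdem.moments import absorb_point, empty_state


@pytest.fixture
def worked_state():
    """The five-point single-attribute class {5, 10, 15, 8, 20}."""
    s = empty_state(1, order=3)
    for v in (5.0, 10.0, 15.0, 8.0, 20.0):
        s = absorb_point(s, [v])
    return s


def random_point_sequences(seed, n_sequences, max_len=50, max_dim=5):
    """Seeded corpus of point sequences in [0, 1]^d for oracle comparisons."""
    rng = np.random.default_rng(seed)
    for _ in range(n_sequences):
        d = int(rng.integers(1, max_dim + 1))
        length = int(rng.integers(2, max_len + 1))
        yield rng.random((length, d))
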