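import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_probs(rng, n, c, h, w):
    """Random valid probability maps (strictly positive, sum to 1)."""
    raw = rng.random((n, c, h, w)) + 0.05
    return raw / raw.sum(axis=1, keepdims=True)


def random_blob(rng, size=32, n_blobs=1):
    """Random union of filled ellipses on a size x size grid (always non-empty)."""
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.ogrid[:size, :size]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(6, size - 6, 2)
        ry, rx = rng.uniform(2.5, 7, 2)
        mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return mask
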