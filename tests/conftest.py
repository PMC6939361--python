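import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


def direct_circular_convolution(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Independent O(d^2) oracle: c[k] = sum_j a[j] * b[(k - j) mod d]."""
    d = len(a)
    c = np.zeros(d)
    for k in range(d):
        for j in range(d):
            c[k] += a[j] * b[(k - j) % d]
    return c


@pytest.fixture(scope="session")
def conv_oracle():
    return direct_circular_convolution


@pytest.fixture(scope="session")
def small_vocab():
    from vsbind import Vocabulary

    return Vocabulary.create(["A", "B", "C", "D"], 256, seed=11)


@pytest.fixture(scope="session")
def item_tags():
    from vsbind import make_tagset

    return make_tagset("item", 256, 8, seed=21)
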