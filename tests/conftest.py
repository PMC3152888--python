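import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from debi import BinaryMatrix, ExpressionMatrix


def ids(prefix, k):
    return [f"{prefix}{i}" for i in range(k)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fig6_matrix():
    """Three disjoint up-regulated blocks over 20 samples.

    Block supports 10/20, 6/20, 4/20; three background genes are all-zero.
    Log2 values: 2.0 inside blocks (4-fold up), 0 elsewhere.
    """
    values = np.zeros((15, 20))
    values[0:5, 0:10] = 2.0   # "red": 5 genes x 10 samples
    values[5:9, 10:16] = 2.0  # "yellow": 4 genes x 6 samples
    values[9:12, 16:20] = 2.0  # "blue": 3 genes x 4 samples
    return ExpressionMatrix(ids("g", 15), ids("s", 20), values)


@pytest.fixture
def fig6_blocks():
    return [
        (frozenset(range(0, 5)), frozenset(range(0, 10))),
        (frozenset(range(5, 9)), frozenset(range(10, 16))),
        (frozenset(range(9, 12)), frozenset(range(16, 20))),
    ]


def binary(bits, direction="as_given"):
    bits = np.asarray(bits, dtype=bool)
    n, m = bits.shape
    return BinaryMatrix(ids("g", n), ids("s", m), bits, direction)


def hypergeom_tail_oracle(sigma_in: int, K: int, n_in: int, M: int) -> float:
    """Exact upper-tail P(X >= sigma_in) by direct enumeration with math.comb.

    Independent of scipy: sums hypergeometric point masses as integer-ratio
    terms.
    """
    denom = math.comb(M, n_in)
    total = 0
    for x in range(max(sigma_in, 0, K - (M - n_in)), min(K, n_in) + 1):
        total += math.comb(K, x) * math.comb(M - K, n_in - x)
    return total / denom
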