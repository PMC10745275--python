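import itertools

import numpy as np
import pytest

import gradme as g
from gradme import bme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_w(n: int, rng) -> np.ndarray:
    """A random valid row-stochastic lower-triangular W."""
    W = np.zeros((n, n))
    W[0, 0] = W[1, 0] = 1.0
    for m in range(2, n):
        x = rng.random(m) + 1e-3
        W[m, :m] = x / x.sum()
    return W


def random_distances(n: int, rng) -> np.ndarray:
    D = rng.random((n, n))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def brute_force_expected_bme(D: np.ndarray, W: np.ndarray, mode: str) -> float:
    """Enumeration oracle: sum_v P(v) f(v) over all ordered vectors."""
    n = len(D)
    total = 0.0
    for v in g.enumerate_ordered_vectors(n):
        p = float(np.prod([W[m, v[m]] for m in range(2, n)]))
        e = bme.path_lengths_from_vector(v, mode)
        total += p * bme.bme_loss(D, e)
    return total


def all_orderings(names):
    for perm in itertools.permutations(range(len(names))):
        yield g.TaxonOrdering(tuple(names), perm)
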