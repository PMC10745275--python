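"""Discrete BME loss and its continuous relaxation."""

import numpy as np
import pytest

import gradme as g
from gradme import bme

from conftest import brute_force_expected_bme, random_distances, random_w


def test_path_lengths_fig_tree_rooted_and_unrooted():
    tree = g.build_tree([0, 0, 0, 2])
    names, e = bme.path_length_matrix(tree, "rooted")
    idx = {nm: i for i, nm in enumerate(names)}
    get = lambda a, b: e[idx[a], idx[b]]
    assert get("0", "2") == 3 and get("2", "3") == 2
    assert get("0", "1") == 3 and get("1", "2") == 4
    names_u, eu = bme.path_length_matrix(tree, "unrooted")
    idx = {nm: i for i, nm in enumerate(names_u)}
    get = lambda a, b: eu[idx[a], idx[b]]
    assert get("0", "1") == 2 and get("1", "2") == 3


def test_path_lengths_three_leaf_star():
    tree = g.build_tree([0, 0, 0])
    _, e = bme.path_length_matrix(tree, "unrooted")
    off = e[np.triu_indices(3, k=1)]
    assert np.all(off == 2)


def test_vector_and_tree_path_lengths_agree(rng):
    for _ in range(20):
        n = int(rng.integers(4, 12))
        v = g.sample_uniform_vector(n, seed=rng)
        for mode in ("rooted", "unrooted"):
            e_vec = bme.path_lengths_from_vector(v, mode)
            names, e_tree = bme.path_length_matrix(g.build_tree(v), mode)
            order = [names.index(str(i)) for i in range(n)]
            assert np.array_equal(e_vec, e_tree[np.ix_(order, order)])


def test_bme_loss_hand_values():
    # 3-leaf star with unit distances: 3 pairs at 2 edges each
    D = np.ones((3, 3)) - np.eye(3)
    _, e = bme.path_length_matrix(g.build_tree([0, 0, 0]), "unrooted")
    assert bme.bme_loss(D, e) == pytest.approx(0.75)
    # quartet ((0,1),(2,3)): within-cherry 0.2, across 0.6
    D = np.full((4, 4), 0.6)
    D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.2
    np.fill_diagonal(D, 0.0)
    e = bme.path_lengths_from_vector([0, 0, 0, 2], "unrooted")
    tree = g.build_tree([0, 0, 0, 2])  # ((0,(2,3)),1) unroots to {2,3}|{0,1}
    names, e_t = bme.path_length_matrix(tree, "unrooted")
    order = [names.index(str(i)) for i in range(4)]
    assert bme.bme_loss(D, e_t[np.ix_(order, order)]) == pytest.approx(0.4)
    # zero distances give zero loss
    assert bme.bme_loss(np.zeros((4, 4)), e) == 0.0


def test_bme_loss_log_space_identical(rng):
    D = random_distances(8, rng)
    e = bme.path_lengths_from_vector(g.sample_uniform_vector(8, seed=1), "rooted")
    a = bme.bme_loss(D, e)
    b = bme.bme_loss(D, e, log_space=True)
    assert a == pytest.approx(b, abs=1e-12)


def test_bme_loss_shape_mismatch():
    with pytest.raises(ValueError):
        bme.bme_loss(np.zeros((3, 3)), np.zeros((4, 4), dtype=int))


def test_w_validation():
    W = g.uniform_w(5)
    bme.validate_w(W)
    bad = W.copy()
    bad[3, 4] = 0.1
    with pytest.raises(ValueError):
        bme.validate_w(bad)
    bad = W.copy()
    bad[2, :2] = [0.7, 0.7]
    with pytest.raises(ValueError):
        bme.validate_w(bad)


def test_expected_terms_hand_n3_uniform():
    """Uniform W on 3 taxa, rooted: averaging the two ordered trees."""
    E = bme.expected_path_terms(g.uniform_w(3), "rooted")
    assert E[0, 1] == pytest.approx(1 / 8)
    assert E[0, 2] == pytest.approx(3 / 16)
    assert E[1, 2] == pytest.approx(3 / 16)
    D = np.ones((3, 3)) - np.eye(3)
    assert bme.expected_bme(D, g.uniform_w(3), "rooted") == pytest.approx(0.5)


def test_point_mass_terms_exact(rng):
    for mode in ("rooted", "unrooted"):
        for _ in range(10):
            n = int(rng.integers(4, 15))
            v = g.sample_uniform_vector(n, seed=rng)
            E = bme.expected_path_terms(g.one_hot_w(v), mode)
            e = bme.path_lengths_from_vector(v, mode)
            expected = np.exp2(-e.astype(float))
            np.fill_diagonal(expected, 0.0)
            assert np.array_equal(E, expected)


@pytest.mark.parametrize("mode", ["rooted", "unrooted"])
@pytest.mark.parametrize("n", [4, 5, 6, 7])
def test_recursion_matches_enumeration(mode, n, rng):
    """E and F agree with the brute-force expectation over all (n-1)! vectors."""
    for _ in range(3):
        W = random_w(n, rng)
        D = random_distances(n, rng)
        f_fast = bme.expected_bme(D, W, mode)
        f_slow = brute_force_expected_bme(D, W, mode)
        assert f_fast == pytest.approx(f_slow, abs=1e-9)


def test_uniform_w_is_mean_over_vectors(rng):
    n = 6
    D = random_distances(n, rng)
    losses = [
        bme.bme_loss(D, bme.path_lengths_from_vector(v, "unrooted"))
        for v in g.enumerate_ordered_vectors(n)
    ]
    assert bme.expected_bme(D, g.uniform_w(n), "unrooted") == pytest.approx(
        np.mean(losses), abs=1e-9
    )


def test_expected_terms_bounds(rng):
    for mode in ("rooted", "unrooted"):
        W = random_w(9, rng)
        E = bme.expected_path_terms(W, mode)
        off = E[np.triu_indices(9, k=1)]
        assert np.all(off > 0) and np.all(off <= 0.5)


def test_scale_equivariance(rng):
    n, c = 7, 3.7
    W = random_w(n, rng)
    D = random_distances(n, rng)
    assert bme.expected_bme(c * D, W, "rooted") == pytest.approx(
        c * bme.expected_bme(D, W, "rooted"), rel=1e-12
    )


def test_gradient_matches_finite_differences(rng):
    h = 1e-6
    for mode in ("rooted", "unrooted"):
        for n in (4, 6, 8):
            W = random_w(n, rng)
            D = random_distances(n, rng)
            gW = bme.grad_expected_bme(D, W, mode)
            for m in range(2, n):
                for j in range(m):
                    Wp, Wm = W.copy(), W.copy()
                    Wp[m, j] += h
                    Wm[m, j] -= h
                    fd = (
                        bme.expected_bme(D, Wp, mode, check=False)
                        - bme.expected_bme(D, Wm, mode, check=False)
                    ) / (2 * h)
                    assert gW[m, j] == pytest.approx(fd, rel=1e-4, abs=1e-9)


def test_gradient_zero_for_zero_distances(rng):
    W = random_w(6, rng)
    assert np.all(bme.grad_expected_bme(np.zeros((6, 6)), W, "rooted") == 0)


def test_per_entry_linearity(rng):
    """Second finite differences vanish: F is linear in every free entry."""
    h = 1e-3
    for n in (5, 8):
        W = random_w(n, rng)
        D = random_distances(n, rng)
        f0 = bme.expected_bme(D, W, "rooted", check=False)
        for m in range(2, n):
            for j in range(m):
                Wp, Wm = W.copy(), W.copy()
                Wp[m, j] += h
                Wm[m, j] -= h
                fp = bme.expected_bme(D, Wp, "rooted", check=False)
                fm = bme.expected_bme(D, Wm, "rooted", check=False)
                assert abs(fp - 2 * f0 + fm) / h**2 <= 1e-6
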