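"""Root placement, balanced branch lengths, ultrametricity."""

import numpy as np
import pytest

import gradme as g
from gradme import bme, rooting


def test_root_scan_three_taxa_hand_case():
    """D01 small, D02 = D12 large: the root belongs on the edge to leaf 2."""
    D = np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]])
    unrooted = g.build_tree([0, 0, 0]).unroot()
    rooted = rooting.root_scan(unrooted, D)
    assert frozenset(["0", "1"]) in rooted.clades()


def test_root_scan_recovers_true_root_on_ultrametric():
    for seed in range(8):
        tree = g.random_ultrametric_tree(10, seed=seed)
        D = g.additive_distances(tree)
        rooted = rooting.root_scan(tree.unroot(), D)
        assert g.rf_distance(rooted, tree, rooted=True) == 0


def test_root_scan_matches_rooted_search(rng):
    """The scan minimum agrees with a full rooted GradME run (small n)."""
    tree = g.random_ultrametric_tree(6, seed=123)
    D = g.additive_distances(tree)
    scan = rooting.root_scan(tree.unroot(), D)
    res = g.run_gradme(D.values, g.OptimizerConfig(mode="rooted", seed=5),
                       taxon_names=D.names)
    names, e = bme.path_length_matrix(scan, mode="rooted")
    idx = [D.names.index(nm) for nm in names]
    scan_loss = bme.bme_loss(D.values[np.ix_(idx, idx)], e)
    assert res.loss == pytest.approx(scan_loss, abs=1e-12)
    assert g.rf_distance(res.tree, scan, rooted=True) == 0


def test_balanced_branch_lengths_additive_recovery():
    tree = g.random_ultrametric_tree(9, seed=4)
    noisy = g.perturb_branch_lengths(tree, 0.5, seed=5)
    D = g.additive_distances(noisy)
    fitted = rooting.balanced_branch_lengths(noisy.unroot(), D)
    refit = g.additive_distances(fitted)
    order = [refit.names.index(nm) for nm in D.names]
    assert np.allclose(refit.values[np.ix_(order, order)], D.values, atol=1e-9)
    assert fitted.floored is False


def test_balanced_branch_lengths_three_leaf_star():
    D = np.full((3, 3), 1.0)
    np.fill_diagonal(D, 0.0)
    star = g.build_tree([0, 0, 0]).unroot()
    fitted = rooting.balanced_branch_lengths(star, D)
    for leaf in fitted.leaves():
        assert leaf.length == pytest.approx(0.5)


def test_balanced_branch_lengths_perturbation_bounded():
    tree = g.random_ultrametric_tree(8, seed=6)
    D = g.additive_distances(tree)
    rng = np.random.default_rng(0)
    noise = rng.uniform(-0.01, 0.01, size=D.values.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0.0)
    Dn = g.DistanceMatrix(D.names, np.clip(D.values + noise, 0, None))
    fitted = rooting.balanced_branch_lengths(tree.unroot(), Dn)
    refit = g.additive_distances(fitted)
    order = [refit.names.index(nm) for nm in Dn.names]
    # fitted tree distances stay within the perturbation scale of the input
    assert np.max(np.abs(refit.values[np.ix_(order, order)] - Dn.values)) < 0.05


def test_midpoint_root_ultrametric_recovers_root():
    for seed in range(5):
        tree = g.random_ultrametric_tree(8, seed=seed)
        rooted = rooting.midpoint_root(tree.unroot())
        assert g.rf_distance(rooted, tree, rooted=True) == 0


def test_midpoint_root_long_pendant():
    from gradme._tree import Tree

    t = g.read_newick("(((a:1,b:1):1,c:1):1,d:10);", from_string=True)
    rooted = rooting.midpoint_root(t)
    # the midpoint lies on the long pendant edge to d: d alone on one side
    sides = [frozenset(l.name for l in Tree(c).leaves()) for c in rooted.root.children]
    assert frozenset(["d"]) in sides


def test_midpoint_root_two_leaves():
    t = g.read_newick("(a:1,b:3);", from_string=True)
    rooted = rooting.midpoint_root(t.copy())
    depths = rooted.depths(weighted=True)
    tips = sorted(depths[l] for l in rooted.leaves())
    assert tips == pytest.approx([2.0, 2.0])


def test_midpoint_root_zero_lengths_error():
    t = g.read_newick("((a:0,b:0):0,c:0);", from_string=True)
    with pytest.raises(g.TreeError):
        rooting.midpoint_root(t)


def test_ultrametricity_cv_examples():
    tree = g.random_ultrametric_tree(6, seed=1)
    assert rooting.ultrametricity_cv(tree) == pytest.approx(0.0, abs=1e-12)
    two = g.read_newick("(a:1,b:3);", from_string=True)
    assert rooting.ultrametricity_cv(two) == pytest.approx(0.5)
    scaled = g.read_newick("(a:10,b:30);", from_string=True)
    assert rooting.ultrametricity_cv(scaled) == pytest.approx(0.5)
    zero = g.read_newick("(a:0,b:0);", from_string=True)
    with pytest.raises(ValueError):
        rooting.ultrametricity_cv(zero)


def test_rooted_unrooted_objective_difference():
    """With a near-constant root-to-taxa column the two objectives differ by
    about the constant root distance."""
    tree = g.random_ultrametric_tree(7, seed=9)
    D = g.additive_distances(tree)
    n = D.n
    d_star = 2.0
    delta = 1e-3
    rng = np.random.default_rng(1)
    root_col = d_star + rng.uniform(-delta, delta, size=n)
    Dx = np.zeros((n + 1, n + 1))
    Dx[:n, :n] = D.values
    Dx[n, :n] = root_col
    Dx[:n, n] = root_col
    # unrooted tree containing the root taxon as leaf n, rooted tree without it
    rooted = tree
    names_r, e_r = bme.path_length_matrix(rooted, mode="rooted")
    idx = [D.names.index(nm) for nm in names_r]
    loss_r = bme.bme_loss(D.values[np.ix_(idx, idx)], e_r)
    # attach the root taxon at the root of the true tree, then unroot
    from gradme._tree import Node, Tree

    ext = tree.copy()
    new_root = Node()
    old = ext.root
    new_root.add_child(old)
    leaf = Node("ROOTTAXON")
    new_root.add_child(leaf)
    ext_tree = Tree(new_root, rooted=True)
    names_u, e_u = bme.path_length_matrix(ext_tree, mode="unrooted")
    order = [(D.names + ["ROOTTAXON"]).index(nm) for nm in names_u]
    loss_u = bme.bme_loss(Dx[np.ix_(order, order)], e_u)
    assert abs(loss_u - loss_r - d_star / 2.0) <= delta
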