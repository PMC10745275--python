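"""Synthetic data generators and evaluation utilities."""

import itertools

import numpy as np
import pytest

import gradme as g
from gradme import rooting


def test_ultrametric_tree_is_ultrametric():
    for seed in range(5):
        tree = g.random_ultrametric_tree(12, total_length=1.0, seed=seed)
        assert rooting.ultrametricity_cv(tree) < 1e-12
        depths = tree.depths(weighted=True)
        for leaf in tree.leaves():
            assert depths[leaf] == pytest.approx(1.0, abs=1e-12)


def test_ultrametric_trees_distinct_across_seeds():
    keys = {
        frozenset(g.random_ultrametric_tree(20, seed=s).clades()) for s in range(20)
    }
    assert len(keys) >= 19


def test_additive_distances_three_point_on_ultrametric():
    tree = g.random_ultrametric_tree(8, seed=3)
    D = g.additive_distances(tree)
    V = D.values
    n = D.n
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = sorted([V[i, j], V[i, k], V[j, k]])
        assert b == pytest.approx(c, abs=1e-9)  # two largest equal


def test_additive_distances_four_point():
    tree = g.build_tree(g.sample_uniform_vector(7, seed=5))
    rng = np.random.default_rng(0)
    for node in tree.preorder():
        if node is not tree.root:
            node.length = float(rng.uniform(0.05, 0.5))
    D = g.additive_distances(tree).values
    n = len(D)
    for i, j, k, l in itertools.combinations(range(n), 4):
        s1 = D[i, j] + D[k, l]
        s2 = D[i, k] + D[j, l]
        s3 = D[i, l] + D[j, k]
        a, b, c = sorted([s1, s2, s3])
        assert b == pytest.approx(c, abs=1e-9)


def test_additive_distances_cherry():
    tree = g.read_newick("(x:1,y:1);", from_string=True)
    D = g.additive_distances(tree)
    assert D.values[0, 1] == pytest.approx(2.0)


def test_perturb_branch_lengths():
    tree = g.random_ultrametric_tree(10, seed=1)
    same = g.perturb_branch_lengths(tree, 0.0, seed=2)
    assert g.rf_distance(tree, same, rooted=True) == 0
    assert rooting.ultrametricity_cv(same) < 1e-12
    noisy = g.perturb_branch_lengths(tree, 0.5, seed=2)
    assert g.rf_distance(tree, noisy, rooted=True) == 0  # topology unchanged
    assert rooting.ultrametricity_cv(noisy) > 0
    with pytest.raises(ValueError):
        g.perturb_branch_lengths(tree, -0.1)


def test_simulate_alignment_zero_lengths_identical():
    tree = g.random_ultrametric_tree(5, seed=0)
    for node in tree.preorder():
        if node is not tree.root:
            node.length = 0.0
    aln = g.simulate_alignment(tree, "JC69", 200, seed=0)
    assert len(set(aln.sequences)) == 1


def test_simulate_alignment_saturation_limit():
    """At a huge JC distance the expected pairwise identity approaches 1/4."""
    from gradme._tree import Node, Tree

    r = Node()
    r.add_child(Node("a", 20.0))
    r.add_child(Node("b", 20.0))
    aln = g.simulate_alignment(Tree(r), "JC69", 20000, seed=1)
    p = g.p_distance(aln).values[0, 1]
    assert p == pytest.approx(0.75, abs=0.02)


def test_simulated_distances_recover_path_lengths():
    tree = g.random_ultrametric_tree(6, total_length=0.4, seed=9)
    aln = g.simulate_alignment(tree, "JC69", 50000, seed=9)
    D = g.closed_form_distance(aln, "JC69")
    truth = g.additive_distances(tree)
    order = [truth.names.index(nm) for nm in D.names]
    expected = truth.values[np.ix_(order, order)]
    assert np.max(np.abs(D.values - expected)) < 0.02


def test_rf_examples():
    t1 = g.read_newick("((0,1),(2,3));", from_string=True)
    t2 = g.read_newick("((0,2),(1,3));", from_string=True)
    assert g.rf_distance(t1, t1.copy()) == 0
    assert g.rf_distance(t1, t2) == 2
    assert g.rf_distance(t1, t2, normalized=True) == 1.0
    assert g.rf_distance(t1, t2) == g.rf_distance(t2, t1)
    assert g.topological_accuracy(t1, t2) == 0.0
    with pytest.raises(g.TreeError):
        g.rf_distance(t1, g.read_newick("((0,1),(2,4));", from_string=True))


def test_rf_rooted_normalization():
    a = g.build_tree([0, 0, 0, 0, 0])
    b = g.build_tree([0, 0, 1, 2, 3])
    d = g.rf_distance(a, b, rooted=True)
    assert 0 < d <= 2 * (5 - 2)
    assert g.rf_distance(a, b, rooted=True, normalized=True) == d / (2 * (5 - 2))


def test_nj_additive_recovery():
    for seed in range(5):
        tree = g.random_ultrametric_tree(10, seed=seed)
        D = g.additive_distances(tree)
        nj = g.neighbor_joining(D)
        assert g.rf_distance(nj, tree) == 0


def test_nj_branch_lengths_additive():
    tree = g.random_ultrametric_tree(8, seed=2)
    D = g.additive_distances(tree)
    nj = g.neighbor_joining(D)
    fitted = g.additive_distances(nj)
    order = [fitted.names.index(nm) for nm in D.names]
    assert np.allclose(fitted.values[np.ix_(order, order)], D.values, atol=1e-9)


def test_nj_quartet_hand_case():
    D = np.array(
        [
            [0, 2, 3, 3],
            [2, 0, 3, 3],
            [3, 3, 0, 2],
            [3, 3, 2, 0],
        ],
        dtype=float,
    )
    nj = g.neighbor_joining(D)
    split = frozenset([frozenset(["0", "1"]), frozenset(["2", "3"])])
    assert split in nj.bipartitions()


def test_nj_matches_dendropy():
    import dendropy

    tree = g.random_ultrametric_tree(9, seed=11)
    noisy = g.perturb_branch_lengths(tree, 0.3, seed=12)
    D = g.additive_distances(noisy)
    mine = g.neighbor_joining(D)

    src = ["," .join([""] + D.names)]
    for name, row in zip(D.names, D.values):
        src.append(",".join([name] + [f"{x:.12f}" for x in row]))
    import io as _io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_io.StringIO("\n".join(src) + "\n"), delimiter=",",
        is_allow_new_taxa=True, taxon_namespace=dendropy.TaxonNamespace(),
    )
    ref = pdm.nj_tree()
    ref_mine = g.read_newick(ref.as_string(schema="newick").replace("[&U] ", ""),
                             from_string=True)
    assert g.rf_distance(mine, ref_mine) == 0
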