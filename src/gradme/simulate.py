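"""Synthetic trees, distances and alignments, plus evaluation utilities.

The tree generator draws coalescent-style ultrametric topologies (uniform
random pair merges with exponential waiting heights) rescaled to a prescribed
height, which emulates the strict-molecular-clock setting in which rooted BME
inference is well posed. Branch-length perturbation adds uniform noise scaled
by the mean branch length to emulate departures from the clock; it does not
emulate rate heterogeneity concentrated in particular clades, so clock tests
here say nothing about lineage-specific rate shifts in real data.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ._tree import Node, Tree, TreeError
from .distances import Alignment, DistanceMatrix
from . import models

__all__ = [
    "random_ultrametric_tree",
    "perturb_branch_lengths",
    "additive_distances",
    "simulate_alignment",
    "rf_distance",
    "topological_accuracy",
    "neighbor_joining",
]


def random_ultrametric_tree(
    n: int, total_length: float = 1.0, seed=None, names: Optional[Sequence[str]] = None
) -> Tree:
    """Random coalescent-style rooted tree with all leaves at depth ``total_length``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if names is None:
        names = [f"t{i}" for i in range(n)]
    nodes = []
    for name in names:
        leaf = Node(name)
        nodes.append((leaf, 0.0))
    height = 0.0
    k = n
    while k > 1:
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        a.length = height - ha
        b.length = height - hb
        nodes = [nodes[x] for x in range(k) if x not in (i, j)] + [(parent, height)]
        k -= 1
    root, h = nodes[0]
    scale = total_length / h
    tree = Tree(root, rooted=True)
    for node in tree.preorder():
        if node.length is not None:
            node.length *= scale
    return tree


def perturb_branch_lengths(tree: Tree, eps: float, seed=None, floor: float = 1e-9) -> Tree:
    """Add U(0, eps * mean-length) noise to every branch; topology unchanged."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = tree.copy()
    if eps == 0:
        return t
    lengths = [n.length or 0.0 for n in t.preorder() if n is not t.root]
    mean = float(np.mean(lengths)) if lengths else 0.0
    for node in t.preorder():
        if node is t.root:
            continue
        noise = rng.uniform(0.0, eps * mean)
        node.length = max((node.length or 0.0) + noise, floor)
    return t


def additive_distances(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length sums of a weighted tree."""
    names, mat = tree.path_lengths(weighted=True)
    return DistanceMatrix(names, np.asarray(mat))


def simulate_alignment(tree: Tree, model: str = "JC69", n_sites: int = 1000, seed=None,
                       freqs=None) -> Alignment:
    """Evolve sequences down ``tree`` under JC69 (DNA) or LG (amino acids).

    The root state is drawn from the stationary (or supplied) frequencies and
    each edge applies the exact matrix-exponential transition probabilities.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    name = model.upper()
    if name == "JC69":
        mdl = models.jc69_model()
        alphabet = "dna"
    elif name == "LG":
        mdl = models.lg_model(freqs)
        alphabet = "protein"
    else:
        raise ValueError(f"unknown simulation model {model!r}")
    k = len(mdl.alphabet)
    states: dict[Node, np.ndarray] = {
        tree.root: rng.choice(k, size=n_sites, p=mdl.freqs)
    }
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = mdl.transition_matrix(node.length or 0.0)
        cum = np.cumsum(P, axis=1)
        parent_states = states[node.parent]
        u = rng.random(n_sites)
        child = (u[:, None] > cum[parent_states]).sum(axis=1)
        states[node] = child
        if node.is_leaf:
            seqs[node.name] = child
    letters = np.array(list(mdl.alphabet))
    names = tree.leaf_names()
    return Alignment(
        names=list(names),
        sequences=["".join(letters[seqs[n]]) for n in names],
        alphabet=alphabet,
    )


def rf_distance(t1: Tree, t2: Tree, normalized: bool = False, rooted: bool = False) -> float:
    """Robinson-Foulds distance: splits (clades when rooted) in exactly one tree.

    The default compares unrooted bipartitions (rooted inputs are unrooted
    first); ``rooted=True`` compares clade sets instead. Normalization divides
    by the binary-tree maximum, 2(n-3) for unrooted and 2(n-2) for rooted
    comparisons.
    """
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise TreeError("trees have different leaf sets")
    n = t1.n_leaves
    if rooted:
        if not (t1.rooted and t2.rooted):
            raise TreeError("rooted comparison requires two rooted trees")
        a, b = t1.clades(), t2.clades()
        denom = 2 * (n - 2)
    else:
        u1 = t1.unroot() if t1.rooted else t1
        u2 = t2.unroot() if t2.rooted else t2
        a, b = u1.bipartitions(), u2.bipartitions()
        denom = 2 * (n - 3)
    raw = len(a ^ b)
    if not normalized:
        return float(raw)
    if denom <= 0:
        return 0.0
    return raw / denom


def topological_accuracy(t1: Tree, t2: Tree, rooted: bool = False) -> float:
    """1 - normalized Robinson-Foulds distance."""
    return 1.0 - rf_distance(t1, t2, normalized=True, rooted=rooted)


def neighbor_joining(D, taxon_names: Optional[Sequence[str]] = None) -> Tree:
    """Classical neighbor joining; deterministic smallest-index tie-break.

    Returns the unrooted topology (trifurcating storage root) with the
    standard NJ branch-length estimates. Recovers the generating tree exactly
    on additive distances.
    """
    if isinstance(D, DistanceMatrix):
        taxon_names = taxon_names or D.names
        D = D.values
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if taxon_names is None:
        taxon_names = [str(i) for i in range(n)]
    nodes = [Node(name) for name in taxon_names]
    d = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # ties -> smallest flat index = smallest (i, j)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    # join the last three at a trifurcating root
    i, j, k = active
    root = Node()
    nodes[i].length = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    nodes[j].length = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    nodes[k].length = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for x in (i, j, k):
        root.add_child(nodes[x])
    return Tree(root, rooted=False)


def nj_loss_tree(D, taxon_names=None):
    """NJ baseline topology and its discrete unrooted BME loss on the same D."""
    from . import bme

    tree = neighbor_joining(D, taxon_names=taxon_names)
    if isinstance(D, DistanceMatrix):
        names_order, e = bme.path_length_matrix(tree, mode="unrooted")
        idx = [D.names.index(nm) for nm in names_order]
        Dv = D.values[np.ix_(idx, idx)]
    else:
        names_order, e = bme.path_length_matrix(tree, mode="unrooted")
        idx = [int(nm) if str(nm).isdigit() else i for i, nm in enumerate(names_order)]
        Dv = np.asarray(D, dtype=float)[np.ix_(idx, idx)]
    return tree, float(bme.bme_loss(Dv, e))
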