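"""Topology-aware reordering of taxa (Queue Shuffle) and NNI moves.

At a fixed taxon ordering only ``(n-1)!`` of the ``(2n-3)!!`` topologies are
expressible as ordered vectors. Queue Shuffle relabels the leaves of the
incumbent tree breadth-first, flipping a fair coin at every internal node to
decide which child inherits the parent's label. The incumbent is expressible
under every ordering produced (so the optimizer's incumbent loss can never
increase), while each of its NNI neighbours is expressible with probability at
least 1/4, so the reachable neighbourhood changes from shuffle to shuffle.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._tree import Node, Tree, TreeError
from .phylo2vec import TaxonOrdering, _relabel

__all__ = ["queue_shuffle", "is_ordered_under", "nni_neighbors", "rooted_nni_neighbors"]


def queue_shuffle(tree: Tree, seed=None) -> tuple[TaxonOrdering, np.ndarray]:
    """Random (ordering, vector) encoding of ``tree``; FIFO label propagation.

    ``seed`` may be an int or a ``numpy.random.Generator`` (the optimizer
    passes a generator so successive shuffles draw from one stream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def choose(a: Node, b: Node) -> int:
        return int(rng.integers(0, 2))

    return _relabel(tree, choose)


def _relabeled_copy(tree: Tree, ordering: TaxonOrdering) -> Tree:
    """Copy of ``tree`` with each leaf's integer label set to sigma(taxon)."""
    label_of = dict(zip(ordering.taxon_names, ordering.sigma))
    t = tree.copy()
    for leaf in t.leaves():
        try:
            leaf.label = label_of[leaf.name]
        except KeyError:
            raise TreeError(f"ordering does not cover taxon {leaf.name!r}") from None
    return t


def is_ordered_under(tree: Tree, ordering: TaxonOrdering) -> bool:
    """True iff ``tree`` is expressible as an ordered vector under ``ordering``.

    Checked by reversing the construction: peel leaves n-1, ..., 2 off a
    relabeled copy; leaf m must be sibling to the pendant leaf it was appended
    to (necessarily carrying a smaller label), else no vector exists.
    """
    tree.validate_binary()
    if not tree.rooted:
        raise TreeError("orderings are defined for rooted trees")
    if set(tree.leaf_names()) != set(ordering.taxon_names):
        raise TreeError("ordering and tree have different taxon sets")
    t = _relabeled_copy(tree, ordering)
    node_of = {leaf.label: leaf for leaf in t.leaves()}
    for m in range(t.n_leaves - 1, 1, -1):
        leaf = node_of[m]
        parent = leaf.parent
        sibling = next(c for c in parent.children if c is not leaf)
        if not sibling.is_leaf or sibling.label > m:
            return False
        # contract: remove leaf m, lift the sibling into the parent slot
        grand = parent.parent
        if grand is None:
            return False
        idx = grand.children.index(parent)
        grand.children[idx] = sibling
        sibling.parent = grand
    return True


def _subtree_sets(tree: Tree) -> dict[Node, frozenset]:
    below: dict[Node, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.name])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
    return below


def _topology_key(tree: Tree) -> frozenset:
    return frozenset(tree.bipartitions())


def nni_neighbors(tree: Tree) -> list[Tree]:
    """All distinct unrooted topologies one NNI move away.

    Accepts a rooted or unrooted tree; neighbours are returned unrooted. Each
    internal edge admits two swaps of the four incident subtrees; trees with
    fewer than 4 leaves have no internal edge and yield an empty list.
    """
    t = tree.unroot() if tree.rooted else tree.copy()
    if t.n_leaves < 4:
        return []
    out: list[Tree] = []
    seen = {_topology_key(t)}
    for child in t.edges():
        if child.is_leaf:
            continue
        parent = child.parent
        # swap each child subtree with a fixed neighbour on the other side;
        # the swap with the remaining neighbour gives the same topology
        others = [c for c in parent.children if c is not child]
        for gc in list(child.children):
            for other in others:
                nt = t.copy()
                pairs = dict(zip(t.preorder(), nt.preorder()))
                a, b = pairs[gc], pairs[other]
                pa, pb = a.parent, b.parent
                ia, ib = pa.children.index(a), pb.children.index(b)
                pa.children[ia], pb.children[ib] = b, a
                a.parent, b.parent = pb, pa
                key = _topology_key(nt)
                if key not in seen:
                    seen.add(key)
                    out.append(nt)
    return out


def rooted_nni_neighbors(tree: Tree) -> list[Tree]:
    """Rooted NNI: for each edge between two non-root internal nodes, swap the
    lower node's children with its sibling subtree (two swaps per edge)."""
    if not tree.rooted:
        raise TreeError("rooted_nni_neighbors expects a rooted tree")
    out: list[Tree] = []
    seen = {frozenset(tree.clades())}
    for child in tree.edges():
        if child.is_leaf or child.parent is tree.root:
            continue
        parent = child.parent
        sibling = next(c for c in parent.children if c is not child)
        for gc in list(child.children):
            nt = tree.copy()
            pairs = dict(zip(tree.preorder(), nt.preorder()))
            a, b = pairs[gc], pairs[sibling]
            pa, pb = a.parent, b.parent
            ia, ib = pa.children.index(a), pb.children.index(b)
            pa.children[ia], pb.children[ib] = b, a
            a.parent, b.parent = pb, pa
            key = frozenset(nt.clades())
            if key not in seen:
                seen.add(key)
                out.append(nt)
    return out
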