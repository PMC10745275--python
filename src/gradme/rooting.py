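"""Root placement for BME trees and ultrametricity diagnostics.

Rooting a topology changes leaf-to-leaf path edge counts (the root vertex
lies on paths that cross it), so the BME loss of a rooted tree depends on
where the root is placed. For (near-)ultrametric distances the rooted-loss
minimizer is the biologically meaningful root — it pushes the root the
maximal distance back in time — and, unlike midpoint rooting, it pools
information from all taxa rather than just the two farthest apart.
"""

from __future__ import annotations

import itertools
from typing import Optional

import numpy as np

from ._tree import Node, Tree, TreeError
from . import bme
from .distances import DistanceMatrix

__all__ = [
    "root_scan",
    "balanced_branch_lengths",
    "midpoint_root",
    "ultrametricity_cv",
]


def _distance_values(D, names: list) -> np.ndarray:
    """Rows of D aligned to ``names``; bare arrays are indexed by digit names."""
    if isinstance(D, DistanceMatrix):
        idx = [D.names.index(nm) for nm in names]
        return D.values[np.ix_(idx, idx)]
    D = np.asarray(D, dtype=float)
    if all(str(nm).isdigit() for nm in names):
        idx = [int(nm) for nm in names]
        return D[np.ix_(idx, idx)]
    return D


def root_scan(tree: Tree, D) -> Tree:
    """Place the root on the edge minimizing the rooted BME loss.

    Evaluates all 2n-3 edges of the unrooted topology (preorder; ties keep
    the earliest edge) and returns the rooted minimizer.
    """
    t = tree.unroot() if tree.rooted else tree
    if t.n_leaves < 3:
        raise TreeError("root scan needs at least 3 leaves")
    best = None
    best_loss = np.inf
    for child in t.edges():
        rooted = t.root_on_edge(child)
        names, e = bme.path_length_matrix(rooted, mode="rooted")
        loss = bme.bme_loss(_distance_values(D, names), e)
        if loss < best_loss:
            best_loss, best = loss, rooted
    return best


def _balanced_averages(tree: Tree, D) -> "tuple[dict, dict]":
    """Memoized balanced (exponentially weighted) averages between subtrees.

    A subtree is a directed edge: ("down", v) is everything below node v,
    ("up", v) is everything else seen across v's parent edge.
    """
    names = tree.leaf_names()
    Dv = _distance_values(D, names)
    index = {nm: i for i, nm in enumerate(names)}

    def parts(side):
        kind, v = side
        if kind == "down":
            if v.is_leaf:
                return None
            return [("down", c) for c in v.children]
        u = v.parent
        sibs = [("down", c) for c in u.children if c is not v]
        if u.parent is not None:
            sibs.append(("up", u))
        if len(sibs) == 1:  # u is the storage root of a rooted tree
            return parts(sibs[0])
        return sibs

    def is_leaf_side(side):
        return side[0] == "down" and side[1].is_leaf

    cache: dict = {}

    def delta(a, b):
        key = (id(a[1]), a[0], id(b[1]), b[0])
        if key in cache:
            return cache[key]
        if is_leaf_side(a) and is_leaf_side(b):
            val = Dv[index[a[1].name], index[b[1].name]]
        elif not is_leaf_side(a):
            p = parts(a)
            val = 0.5 * (delta(p[0], b) + delta(p[1], b))
        else:
            p = parts(b)
            val = 0.5 * (delta(a, p[0]) + delta(a, p[1]))
        cache[key] = val
        cache[(key[2], key[3], key[0], key[1])] = val
        return val

    return delta, parts


def balanced_branch_lengths(tree: Tree, D, floor: bool = True) -> Tree:
    """Balanced (Pauplin-weighted) least-squares edge lengths for a topology.

    Returns a copy of ``tree`` with lengths assigned; negative estimates are
    floored at zero when ``floor`` (the copy records the flooring in
    ``tree.floored``). Exact on additive distances.
    """
    t = tree.copy()
    delta, parts = _balanced_averages(t, D)
    floored = False
    for child in t.edges():
        down = ("down", child)
        up = ("up", child)
        if child.is_leaf:
            a, b = parts(up)
            length = 0.5 * (delta(down, a) + delta(down, b) - delta(a, b))
        else:
            c, d = parts(down)
            a, b = parts(up)
            length = 0.25 * (
                delta(a, c) + delta(a, d) + delta(b, c) + delta(b, d)
            ) - 0.5 * (delta(a, b) + delta(c, d))
        if floor and length < 0:
            length = 0.0
            floored = True
        child.length = float(length)
    t.floored = floored
    return t


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf weighted path."""
    if tree.n_leaves == 2:
        a, b = tree.leaves()
        total = (a.length or 0.0) + (b.length or 0.0)
        if total <= 0:
            raise TreeError("all path lengths are zero; midpoint undefined")
        root = Node()
        root.add_child(Node(a.name, total / 2.0))
        root.add_child(Node(b.name, total / 2.0))
        return Tree(root, rooted=True)
    t = tree.unroot() if tree.rooted else tree.copy()
    for node in t.preorder():
        if node is not t.root and node.length is not None and node.length < 0:
            raise TreeError("midpoint rooting requires non-negative lengths")
    names, mat = t.path_lengths(weighted=True)
    mat = np.asarray(mat)
    if float(mat.max()) <= 0:
        raise TreeError("all path lengths are zero; midpoint undefined")
    i, j = np.unravel_index(np.argmax(mat), mat.shape)
    leaves = {leaf.name: leaf for leaf in t.leaves()}
    li, lj = leaves[names[i]], leaves[names[j]]
    # node chains to the storage root
    def chain(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    ci, cj = chain(li), chain(lj)
    in_cj = set(id(x) for x in cj)
    lca = next(x for x in ci if id(x) in in_cj)
    up_path = ci[: ci.index(lca)]  # nodes strictly below lca on i's side
    down_path = list(reversed(cj[: cj.index(lca)]))  # lca side -> j
    # edges along the path ordered from i to j: (child_node, parent_closer_to_i)
    edges = [(node, False) for node in up_path] + [(node, True) for node in down_path]
    total = float(mat[i, j])
    half = total / 2.0
    cum = 0.0
    for child, parent_first in edges:
        length = child.length or 0.0
        if cum + length >= half or (child, parent_first) == edges[-1]:
            if length == 0:
                fraction = 0.5
            else:
                offset = half - cum  # distance from the i-side end of this edge
                fraction = offset / length if parent_first else 1.0 - offset / length
            fraction = min(max(fraction, 0.0), 1.0)
            return t.root_on_edge(child, fraction)
        cum += length
    raise AssertionError("midpoint not located")  # pragma: no cover


def ultrametricity_cv(tree: Tree) -> float:
    """Coefficient of variation (population sd / mean) of root-to-tip lengths."""
    if not tree.rooted:
        raise TreeError("ultrametricity is defined for rooted trees")
    depths = tree.depths(weighted=True)
    tips = np.array([depths[leaf] for leaf in tree.leaves()])
    mean = float(tips.mean())
    if mean == 0:
        raise ValueError("zero mean root-to-tip length")
    return float(tips.std() / mean)
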