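"""Ordered integer-vector encoding of rooted binary trees.

A tree on ``n`` taxa is encoded by a vector ``v`` with ``v[0] == v[1] == 0``
and ``v[m]`` in ``{0, ..., m-1}``: starting from the two-leaf tree with pendant
edges labeled 0 and 1, leaf ``m`` is attached by subdividing the pendant edge
labeled ``v[m]``. The map is a bijection between valid vectors of length ``n``
and *ordered* trees, a subset of size ``(n-1)!`` of all ``(2n-3)!!`` rooted
topologies. A taxon ordering (a permutation of processing labels) selects
which subset of tree space the encoding can reach.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from ._tree import Node, Tree, TreeError

__all__ = [
    "TaxonOrdering",
    "validate_ordered",
    "build_tree",
    "tree_to_vector",
    "sample_uniform_vector",
    "enumerate_ordered_vectors",
    "count_topologies",
    "count_ordered",
    "remove_root",
    "expected_leaf_depths",
]


@dataclass(frozen=True)
class TaxonOrdering:
    """Permutation sigma assigning a processing label to each taxon.

    ``sigma[i]`` is the integer label under which the taxon named
    ``taxon_names[i]`` is processed by the vector encoding.
    """

    taxon_names: tuple
    sigma: tuple

    def __post_init__(self):
        n = len(self.taxon_names)
        if sorted(self.sigma) != list(range(n)):
            raise ValueError("sigma is not a permutation of 0..n-1")
        if len(set(self.taxon_names)) != n:
            raise ValueError("taxon names are not unique")

    @property
    def n(self) -> int:
        return len(self.taxon_names)

    @classmethod
    def identity(cls, n: int, names: Optional[Sequence[str]] = None) -> "TaxonOrdering":
        if names is None:
            names = [str(i) for i in range(n)]
        return cls(tuple(names), tuple(range(n)))

    def name_of_label(self, label: int) -> str:
        return self.taxon_names[self.inverse()[label]]

    def inverse(self) -> tuple:
        inv = [0] * self.n
        for i, a in enumerate(self.sigma):
            inv[a] = i
        return tuple(inv)

    def relabel(self, sigma: Sequence[int]) -> "TaxonOrdering":
        return TaxonOrdering(self.taxon_names, tuple(sigma))


def validate_ordered(v: Sequence[int]) -> bool:
    """True iff ``v`` is a valid ordered vector (v0 = v1 = 0, vm <= m-1)."""
    v = list(v)
    if len(v) < 2:
        raise ValueError("an ordered vector has length >= 2")
    if any(int(x) != x for x in v):
        return False
    if v[0] != 0 or v[1] != 0:
        return False
    return all(0 <= v[m] <= m - 1 for m in range(2, len(v)))


def _check_vector(v: Sequence[int]) -> np.ndarray:
    v = np.asarray(v, dtype=int)
    if not validate_ordered(v):
        raise ValueError(f"not a valid ordered vector: {v.tolist()}")
    return v


def build_tree(v: Sequence[int], ordering: Optional[TaxonOrdering] = None) -> Tree:
    """Construct the rooted topology encoded by ``v`` under ``ordering``.

    Runs in O(n). Leaf names are taken from the ordering (label ``a`` receives
    the name of the taxon with ``sigma[i] == a``); the identity ordering with
    names "0", "1", ... is used when none is given.
    """
    v = _check_vector(v)
    n = len(v)
    if ordering is None:
        ordering = TaxonOrdering.identity(n)
    if ordering.n != n:
        raise ValueError("ordering length does not match vector length")

    root = Node()
    pendant: dict[int, Node] = {}
    for lab in (0, 1):
        leaf = Node()
        leaf.label = lab
        root.add_child(leaf)
        pendant[lab] = leaf
    for m in range(2, n):
        old_leaf = pendant[int(v[m])]
        parent = old_leaf.parent
        fork = Node()
        idx = parent.children.index(old_leaf)
        parent.children[idx] = fork
        fork.parent = parent
        fork.add_child(old_leaf)
        new_leaf = Node()
        new_leaf.label = m
        fork.add_child(new_leaf)
        pendant[m] = new_leaf
    inv = ordering.inverse()
    for leaf in pendant.values():
        leaf.name = ordering.taxon_names[inv[leaf.label]]
    return Tree(root, rooted=True)


def _relabel(tree: Tree, choose_inheritor: Callable[[Node, Node], int]) -> tuple[TaxonOrdering, np.ndarray]:
    """Label a rooted binary tree breadth-first and read off its vector.

    Internal nodes are processed through a FIFO queue seeded with the root
    (label 0). Processing a node with label ``x`` gives one child
    (``choose_inheritor`` returns its index) the label ``x`` and the other the
    smallest unused label; internal children are enqueued inheritor-first, so
    nodes are processed in non-decreasing generation. The fresh label ``m``
    introduced at a node with label ``x`` yields ``v[m] = x``.
    """
    tree.validate_binary()
    if not tree.rooted:
        raise TreeError("labeling requires a rooted binary tree")
    n = tree.n_leaves
    if n < 2:
        raise TreeError("need at least 2 leaves")
    labels: dict[Node, int] = {tree.root: 0}
    intro_at: dict[int, int] = {}
    queue: list[Node] = [tree.root]
    head = 0
    next_label = 1
    while head < len(queue):
        node = queue[head]
        head += 1
        x = labels[node]
        a, b = node.children
        keep = choose_inheritor(a, b)
        inheritor, other = (a, b) if keep == 0 else (b, a)
        labels[inheritor] = x
        labels[other] = next_label
        intro_at[next_label] = x
        next_label += 1
        # inheritor goes immediately ahead of its sibling
        for child in (inheritor, other):
            if not child.is_leaf:
                queue.append(child)
    v = np.zeros(n, dtype=int)
    for m in range(2, n):
        v[m] = intro_at[m]
    leaves = tree.leaves()
    names = tuple(leaf.name if leaf.name is not None else str(i) for i, leaf in enumerate(leaves))
    sigma = tuple(labels[leaf] for leaf in leaves)
    return TaxonOrdering(names, sigma), v


def _min_leaf_name(node: Node) -> str:
    return min(l.name if l.name is not None else "" for l in Tree(node).leaves())


def tree_to_vector(tree: Tree) -> tuple[TaxonOrdering, np.ndarray]:
    """Canonical (ordering, vector) encoding of a rooted binary topology.

    Deterministic: at each node the child whose leaf-name set is
    lexicographically smallest inherits the parent's label. The returned pair
    satisfies ``build_tree(v, ordering) == tree`` up to topology.
    """

    def choose(a: Node, b: Node) -> int:
        return 0 if _min_leaf_name(a) <= _min_leaf_name(b) else 1

    return _relabel(tree, choose)


def sample_uniform_vector(n: int, seed=None) -> np.ndarray:
    """Draw each entry ``v[m]`` (m >= 2) independently uniformly on {0..m-1}."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    v = np.zeros(n, dtype=int)
    for m in range(2, n):
        v[m] = rng.integers(0, m)
    return v


def enumerate_ordered_vectors(n: int) -> Iterator[np.ndarray]:
    """Yield all ``(n-1)!`` valid ordered vectors of length ``n``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    for tail in itertools.product(*(range(m) for m in range(2, n))):
        yield np.array((0, 0) + tail, dtype=int)


def count_topologies(n: int) -> int:
    """Number of rooted binary topologies on n labeled leaves: (2n-3)!!."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return math.prod(range(1, 2 * n - 2, 2))


def count_ordered(n: int) -> int:
    """Number of ordered trees on n leaves at a fixed ordering: (n-1)!."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return math.factorial(n - 1)


def remove_root(tree: Tree) -> Tree:
    """Suppress the degree-2 root, returning the unrooted topology."""
    if tree.n_leaves < 3:
        raise TreeError("unrooted binary trees need at least 3 leaves")
    return tree.unroot()


def expected_leaf_depths(n: int) -> list[Fraction]:
    """Exact expected root-to-leaf edge depths under the uniform vector law.

    Appending leaf ``k`` deepens each existing leaf's pendant edge with
    probability 1/k and places the new leaf one edge below a uniformly chosen
    pendant, giving ``E[d_0] = H_{n-1}`` (harmonic growth) and a late-to-early
    depth ratio approaching 2.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    d = [Fraction(1), Fraction(1)]
    for k in range(2, n):
        mean = sum(d) / k
        d = [x + Fraction(1, k) for x in d]
        d.append(1 + mean)
    return d
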