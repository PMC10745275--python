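"""Minimal rooted/unrooted binary tree container.

Trees are stored as mutable node structures with parent pointers. A rooted
binary topology has a degree-2 root; an unrooted topology is stored rooted at
an arbitrary internal vertex of degree 3 (the usual trifurcating-root
convention). Leaf nodes carry taxon names; edges carry the length of the edge
to the node's parent (``None`` when lengths are absent).
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class Node:
    __slots__ = ("children", "parent", "name", "length", "label")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.name = name
        self.length = length
        self.label: Optional[int] = None  # scratch slot for integer labelings

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name!r} children={len(self.children)}>"


class Tree:
    """A rooted tree; ``rooted=False`` marks the trifurcating-root convention."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # ------------------------------------------------------------------ #
    # traversal and basic queries
    # ------------------------------------------------------------------ #
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def validate_binary(self) -> None:
        """Check binary arity: root degree 2 (rooted) or 3 (unrooted), others 3."""
        for node in self.preorder():
            if node.is_leaf:
                continue
            k = len(node.children)
            want = (2 if self.rooted else 3) if node is self.root else 2
            if k != want:
                kind = "root" if node is self.root else "internal node"
                raise TreeError(f"{kind} has {k} children, expected {want}")
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf names")

    # ------------------------------------------------------------------ #
    # copying
    # ------------------------------------------------------------------ #
    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.label = node.label
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Tree(rec(self.root), rooted=self.rooted)

    # ------------------------------------------------------------------ #
    # path lengths and depths
    # ------------------------------------------------------------------ #
    def depths(self, weighted: bool = False) -> dict[Node, float]:
        d: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            step = (node.length or 0.0) if weighted else 1.0
            d[node] = d[node.parent] + step
        return d

    def path_lengths(self, weighted: bool = False) -> tuple[list[str], "list[list[float]]"]:
        """All leaf-to-leaf path lengths via LCA depths.

        Returns leaf names (in traversal order) and the symmetric matrix.
        """
        leaves = self.leaves()
        depth = self.depths(weighted=weighted)
        anc: dict[Node, list[Node]] = {}
        for leaf in leaves:
            chain = []
            node: Optional[Node] = leaf
            while node is not None:
                chain.append(node)
                node = node.parent
            anc[leaf] = chain
        index = {leaf: set(chain) for leaf, chain in anc.items()}
        n = len(leaves)
        mat = [[0.0] * n for _ in range(n)]
        for i, j in itertools.combinations(range(n), 2):
            li, lj = leaves[i], leaves[j]
            lca = next(node for node in anc[li] if node in index[lj])
            val = depth[li] + depth[lj] - 2.0 * depth[lca]
            mat[i][j] = mat[j][i] = val
        return [l.name for l in leaves], mat

    # ------------------------------------------------------------------ #
    # splits / clades (for Robinson-Foulds style comparison)
    # ------------------------------------------------------------------ #
    def clades(self) -> set[frozenset[str]]:
        """Non-trivial clades (rooted comparison): one per non-root internal node."""
        out: set[frozenset[str]] = set()
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
                if node is not self.root:
                    out.add(below[node])
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions of the leaf set induced by internal edges."""
        all_names = frozenset(self.leaf_names())
        out: set[frozenset[frozenset[str]]] = set()
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = below[node]
            other = all_names - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset([side, other]))
        return out

    # ------------------------------------------------------------------ #
    # rooting manipulations
    # ------------------------------------------------------------------ #
    def unroot(self) -> "Tree":
        """Suppress a degree-2 root, fusing its two incident edges."""
        if not self.rooted:
            return self.copy()
        if self.n_leaves < 3:
            raise TreeError("cannot unroot a tree with fewer than 3 leaves")
        t = self.copy()
        a, b = t.root.children
        # keep an internal child as the new trifurcating root
        keep, other = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            raise TreeError("no internal node adjacent to the root")
        fused = None
        if other.length is not None or keep.length is not None:
            fused = (other.length or 0.0) + (keep.length or 0.0)
        other.length = fused
        keep.parent = None
        keep.length = None
        keep.children.append(other)
        other.parent = keep
        return Tree(keep, rooted=False)

    def edges(self) -> list[Node]:
        """Edges in preorder, each identified by its child node."""
        return [n for n in self.preorder() if n is not self.root]

    def root_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a rooted copy with the root subdividing the edge above `child`.

        `child` must be a node of an unrooted self. `fraction` is the portion of
        the edge length assigned to the side of `child`'s old parent.
        """
        if self.rooted:
            raise TreeError("root_on_edge expects an unrooted tree")
        # map nodes of self to the copy
        t = self.copy()
        pairs = dict(zip(self.preorder(), t.preorder()))
        child = pairs[child]
        old_parent = child.parent
        if old_parent is None:
            raise TreeError("cannot root above the storage root")
        length = child.length
        old_parent.children.remove(child)
        new_root = Node()
        new_root.add_child(child)
        if length is not None:
            child.length = (1.0 - fraction) * length
        # reverse parent pointers along the path old_parent -> storage root
        prev = new_root
        prev_len = None if length is None else fraction * length
        node: Optional[Node] = old_parent
        while node is not None:
            nxt = node.parent
            nxt_len = node.length
            if nxt is not None:
                nxt.children.remove(node)
            node.parent = None
            prev.add_child(node)
            node.length = prev_len
            prev, prev_len, node = node, nxt_len, nxt
        _suppress_unary(new_root)
        return Tree(new_root, rooted=True)


def _suppress_unary(root: Node) -> None:
    """Remove degree-2 non-root vertices created by re-rooting, in place."""
    stack = list(root.children)
    while stack:
        node = stack.pop()
        if not node.is_leaf and len(node.children) == 1:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
            stack.append(child)
        else:
            stack.extend(node.children)
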