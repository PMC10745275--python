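"""File formats: FASTA alignments, PHYLIP square distance matrices, Newick trees.

Newick parsing and serialization are delegated to dendropy; trees cross the
boundary through :func:`to_dendropy` / :func:`from_dendropy`.
"""

from __future__ import annotations

from typing import Optional

import dendropy
import numpy as np
from Bio import SeqIO

from ._tree import Node, Tree, TreeError
from .distances import Alignment, DistanceMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_phylip_distance",
    "write_phylip_distance",
    "read_newick",
    "write_newick",
    "to_dendropy",
    "from_dendropy",
]

_DNA_CHARS = set("ACGTUNRYSWKMBDHV-.?")


def _detect_alphabet(seqs: list) -> str:
    chars = set("".join(seqs).upper())
    return "dna" if chars <= _DNA_CHARS else "protein"


def read_fasta(path, alphabet: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA file; alphabet auto-detected unless given."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    names = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate sequence names in {path}: {dupes}")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError(f"ragged alignment in {path}: unequal sequence lengths")
    return Alignment(names, seqs, alphabet or _detect_alphabet(seqs))


def write_fasta(aln: Alignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.names, aln.sequences):
            fh.write(f">{name}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


def read_phylip_distance(path) -> DistanceMatrix:
    """Square PHYLIP distance matrix: first line n, then name + n reals."""
    with open(path) as fh:
        tokens_lines = [line.split() for line in fh if line.strip()]
    if not tokens_lines:
        raise ValueError(f"empty distance file {path}")
    try:
        n = int(tokens_lines[0][0])
    except ValueError:
        raise ValueError(f"{path}: first line must give the number of taxa") from None
    rows = tokens_lines[1:]
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(rows)}")
    names, values = [], []
    for row in rows:
        if len(row) != n + 1:
            raise ValueError(f"{path}: row {row[0]!r} has {len(row) - 1} values, expected {n}")
        names.append(row[0])
        values.append([float(x) for x in row[1:]])
    values = np.asarray(values)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError(f"{path}: matrix is not symmetric within 1e-8")
    return DistanceMatrix(names, (values + values.T) / 2.0)


def write_phylip_distance(D: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for name, row in zip(D.names, D.values):
            vals = " ".join(f"{x:.10g}" for x in row)
            fh.write(f"{name} {vals}\n")


# --------------------------------------------------------------------- #
# Newick via dendropy
# --------------------------------------------------------------------- #
def to_dendropy(tree: Tree, taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
    ns = taxon_namespace or dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=ns)

    def rec(node: Node, dnode):
        dnode.edge.length = node.length
        if node.is_leaf:
            dnode.taxon = ns.require_taxon(label=node.name)
        for child in node.children:
            rec(child, dnode.new_child())

    rec(tree.root, dt.seed_node)
    dt.is_rooted = tree.rooted
    return dt


def from_dendropy(dtree: dendropy.Tree) -> Tree:
    def rec(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(name, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    root = rec(dtree.seed_node)
    root.length = None
    k = len(root.children)
    if k not in (2, 3):
        raise TreeError(f"top-level degree {k}: expected bifurcating (rooted) or trifurcating (unrooted)")
    return Tree(root, rooted=(k == 2))


def read_newick(source, from_string: bool = False) -> Tree:
    """Parse Newick from a path (or a literal string with ``from_string``)."""
    try:
        if from_string:
            dt = dendropy.Tree.get(data=source, schema="newick")
        else:
            dt = dendropy.Tree.get(path=str(source), schema="newick")
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return from_dendropy(dt)


def write_newick(tree: Tree, path=None) -> str:
    """Serialize to Newick; writes to ``path`` when given, returns the string."""
    dt = to_dendropy(tree)
    s = dt.as_string(schema="newick", suppress_rooting=True, real_value_format_specifier=".10g")
    s = s.strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
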