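"""p-distances, UPGMA clustering and rooted ultrametric trees.

The dissimilarity feeding the clustering is the p-distance — the proportion of
mismatching positions between two equal-length character strings — applied
either to the nucleotide alignment (SNP mode) or to the binary A/T matrix of
recoded CpG sites (CpG mode). No multiple-hit correction is applied.

UPGMA (unweighted pair group method with arithmetic mean) is implemented
classically: at each step the two closest clusters merge at height d/2, and the
merged cluster's distance to any other is the size-weighted arithmetic mean of
its members' distances. Under the implied molecular clock the result is a
rooted, ultrametric, binary tree. Ties in the closest-pair search are broken
deterministically by the smallest pair of cluster positions in label order, so
identical inputs always produce the identical tree.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import DistanceError, TreeComparisonError
from .msa_io import GAP_CHARS

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance_matrix",
    "upgma",
    "to_newick",
    "from_newick",
    "topology_equal",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise dissimilarities with taxon labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if n < 2:
            raise DistanceError("need at least 2 taxa")
        if d.shape != (n, n):
            raise DistanceError(f"matrix shape {d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(d)):
            raise DistanceError("distances must be finite (no NaN/inf)")
        if np.any(d < 0):
            raise DistanceError("distances must be nonnegative")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DistanceError("matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise DistanceError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df.to_numpy(dtype=float))


class TreeNode:
    """A node of a rooted tree.

    ``height`` is the node's ultrametric height above the leaves (leaves are at
    0); ``length`` is the branch length to the parent (None at the root).
    General trees parsed from Newick may carry lengths without heights.
    """

    __slots__ = ("label", "children", "height", "length")

    def __init__(self, label=None, children=(), height=None, length=None):
        self.label = label
        self.children: list[TreeNode] = list(children)
        self.height = height
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> "Iterator[TreeNode]":
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"TreeNode({self.label!r}, h={self.height}, l={self.length})"


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class Tree:
    """A rooted (binary, for UPGMA output) tree over labelled leaves."""

    root: TreeNode

    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.label for leaf in self.root.leaves())

    def clades(self) -> "frozenset[frozenset[str]]":
        """Leaf-label sets of every internal node (the rooted cluster sets)."""
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            s = frozenset().union(*(walk(c) for c in node.children))
            out.add(s)
            return s

        walk(self.root)
        return frozenset(out)

    def leaf_depths(self) -> "dict[str, float]":
        """Root-to-leaf path lengths (requires branch lengths)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                depths[node.label] = depth
            for child in node.children:
                if child.length is None:
                    raise DistanceError(f"branch above {child.label!r} has no length")
                walk(child, depth + child.length)

        walk(self.root, 0.0)
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.leaf_depths().values()
        return (max(depths) - min(depths)) <= tol

    def total_branch_length(self) -> float:
        total = 0.0

        def walk(node: TreeNode) -> None:
            nonlocal total
            for child in node.children:
                total += child.length or 0.0
                walk(child)

        walk(self.root)
        return total

    def clade_heights(self) -> "dict[frozenset[str], float]":
        """Ultrametric height of every internal clade (requires heights)."""
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            s = frozenset().union(*(walk(c) for c in node.children))
            if node.height is None:
                raise DistanceError("tree has no node heights")
            out[s] = node.height
            return s

        walk(self.root)
        return out

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise leaf distances implied by the tree: 2 x LCA height."""
        labels = self.leaf_names()
        index = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [walk(c) for c in node.children]
            if node.height is None:
                raise DistanceError("tree has no node heights")
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[index[a], index[b]] = d[index[b], index[a]] = (
                                2.0 * node.height
                            )
            return [lab for g in groups for lab in g]

        walk(self.root)
        return DistanceMatrix(labels, d)

    def to_newick(self, decimals: int = 6) -> str:
        return to_newick(self, decimals)


def _rows_and_labels(seqs) -> "tuple[tuple[str, ...], tuple[str, ...]]":
    """Accept AlignedSeqSet, EpiMatrix, mapping or (labels, rows) pair."""
    if hasattr(seqs, "labels") and hasattr(seqs, "rows"):
        return tuple(seqs.labels), tuple(seqs.rows)
    if hasattr(seqs, "labels") and hasattr(seqs, "characters"):
        return tuple(seqs.labels), tuple(seqs.characters)
    if isinstance(seqs, Mapping):
        return tuple(seqs.keys()), tuple(str(v) for v in seqs.values())
    labels, rows = seqs
    return tuple(labels), tuple(str(r) for r in rows)


def p_distance_matrix(seqs, ignore_gaps: bool = True) -> DistanceMatrix:
    """Pairwise p-distances (proportion of mismatching positions).

    With ``ignore_gaps`` (default), positions where either sequence has ``-``
    or ``N`` are dropped from both numerator and denominator of that pair; a
    pair left with zero comparable positions raises :class:`DistanceError`.
    """
    labels, rows = _rows_and_labels(seqs)
    if len(rows) < 2:
        raise DistanceError("need at least 2 sequences")
    length = len(rows[0])
    if length < 1 or any(len(r) != length for r in rows):
        raise DistanceError("sequences must share one nonzero length")
    M = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(
        len(rows), length
    )
    if ignore_gaps:
        gap_codes = np.frombuffer(
            "".join(sorted(GAP_CHARS)).encode(), dtype=np.uint8
        )
        valid = ~np.isin(M, gap_codes)
    else:
        valid = np.ones_like(M, dtype=bool)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise DistanceError(
                    f"no comparable positions between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int(((M[i] != M[j]) & both).sum())
            d[i, j] = d[j, i] = mism / n_comp
    return DistanceMatrix(labels, d)


def upgma(dm: DistanceMatrix) -> Tree:
    """Classical (size-weighted) UPGMA on a distance matrix.

    Merges the closest pair of clusters at height d/2; the new cluster's
    distance to any other is the arithmetic mean of member distances, weighted
    by cluster sizes. Tie-break: the pair with the smallest (i, j) position in
    the current cluster order (which starts as label order; a merged cluster
    takes the position of its first member).
    """
    n = len(dm.labels)
    D = dm.d.astype(float).copy()
    nodes = [TreeNode(label=lab, height=0.0) for lab in dm.labels]
    sizes = [1] * n
    active = list(range(n))  # positions into nodes/sizes/D

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                dist = D[active[ai], active[aj]]
                if best is None or dist < best[0]:
                    best = (dist, ai, aj)
        dist, ai, aj = best
        p, q = active[ai], active[aj]
        h = dist / 2.0
        left, right = nodes[p], nodes[q]
        left.length = h - left.height
        right.length = h - right.height
        parent = TreeNode(children=(left, right), height=h)
        # Size-weighted average distance to all remaining clusters.
        for r in active:
            if r in (p, q):
                continue
            newd = (sizes[p] * D[p, r] + sizes[q] * D[q, r]) / (sizes[p] + sizes[q])
            D[p, r] = D[r, p] = newd
        nodes[p] = parent
        sizes[p] += sizes[q]
        active.pop(aj)
    root = nodes[active[0]]
    return Tree(root)


def to_newick(tree: Tree, decimals: int = 6) -> str:
    """Serialise a rooted tree with branch lengths as Newick (';'-terminated)."""

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = _quote_label(str(node.label))
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.label:
                body += _quote_label(str(node.label))
        if not top and node.length is not None:
            body += f":{node.length:.{decimals}f}"
        return body

    return fmt(tree.root, True) + ";"


def from_newick(text: str) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    If the tree is ultrametric (all root-to-leaf depths equal within 1e-6),
    node heights are filled in from the depths; otherwise heights stay None.
    """
    dtree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return TreeNode(
            label=label,
            children=children,
            length=dnode.edge.length,
        )

    tree = Tree(convert(dtree.seed_node))
    try:
        depths = tree.leaf_depths()
    except DistanceError:
        return tree
    height = max(depths.values())
    if height > 0 and (height - min(depths.values())) <= 1e-6 * max(1.0, height):

        def set_heights(node: TreeNode, depth: float) -> None:
            node.height = 0.0 if node.is_leaf else height - depth
            for child in node.children:
                set_heights(child, depth + (child.length or 0.0))

        set_heights(tree.root, 0.0)
    return tree


def topology_equal(t1: Tree, t2: Tree) -> bool:
    """True iff the rooted cluster sets of the two trees are identical.

    Branch lengths are ignored. Raises :class:`TreeComparisonError` when the
    leaf sets differ.
    """
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise TreeComparisonError(
            f"leaf sets differ: {sorted(l1 ^ l2)} not shared"
        )
    return t1.clades() == t2.clades()
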