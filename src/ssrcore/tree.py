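"""UPGMA clustering and the ultrametric dendrogram it produces.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the closest pair of clusters; the distance from a merged cluster to any
other is the size-weighted arithmetic mean of its members' distances, and a
merge at distance ``d_min`` creates a node at height ``d_min / 2``, so the
result is ultrametric.  Ties are broken on the lowest (row, column) index
pair of the current matrix, which makes trees deterministic for a fixed
input order.

Cherries — internal nodes whose two children are both leaves — are the
groups "at the lowest level" used by the stepwise core-collection selection
(:mod:`ssrcore.core`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .errors import InfiniteDistanceError, ValidationError

__all__ = ["Node", "Dendrogram", "upgma", "to_newick", "cophenetic"]


@dataclass
class Node:
    """Dendrogram node; a leaf iff ``children`` is empty."""

    height: float
    children: tuple["Node", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def size(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.size for c in self.children)

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Rooted binary ultrametric tree over accession leaves."""

    root: Node

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return self.root.size

    def cherries(self) -> list[Node]:
        """Internal nodes with two leaf children, in merge (height) order of discovery."""
        found: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                return
            if all(c.is_leaf for c in node.children):
                found.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return found

    def newick(self, fmt=str) -> str:
        return to_newick(self, fmt=fmt)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Build the UPGMA dendrogram of a distance matrix.

    Node heights are half the merge distance; ties go to the lowest
    (row, column) pair.  Infinite distances must be resolved upstream.
    """
    n = dm.n
    if n < 2:
        raise ValidationError("UPGMA needs at least two items")
    if not np.all(np.isfinite(dm.d)):
        raise InfiniteDistanceError("distance matrix contains non-finite entries")

    d = dm.d.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    nodes: list[Node | None] = [Node(0.0, label=i) for i in dm.ids]
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)

    for _ in range(n - 1):
        # row-major argmin scans (0,0),(0,1),... so the first minimum is the
        # lowest (row, column) pair — the tie rule
        flat = np.argmin(d)
        i, j = divmod(int(flat), n)
        if i > j:  # the (i<j) copy occurs first row-major; guard anyway
            i, j = j, i
        h = d[i, j] / 2.0
        merged = Node(h, children=(nodes[i], nodes[j]))
        # merged cluster takes slot i (the lower index)
        wi, wj = sizes[i], sizes[j]
        new_row = (wi * d[i, :] + wj * d[j, :]) / (wi + wj)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = np.inf
        d[j, :] = np.inf
        d[:, j] = np.inf
        nodes[i] = merged
        nodes[j] = None
        sizes[i] = wi + wj
        active[j] = False

    (root_idx,) = np.flatnonzero(active)
    return Dendrogram(nodes[root_idx])


def to_newick(tree: Dendrogram, fmt=str) -> str:
    """Serialise to Newick; branch length = parent height - child height."""

    def render(node: Node, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{fmt(float(parent_height - node.height))}"

    return render(tree.root, None) + ";"


def cophenetic(tree: Dendrogram) -> DistanceMatrix:
    """Leaf-pair cophenetic distances (2x the MRCA height; ultrametric)."""
    labels = tree.leaf_labels()
    index = {lbl: k for k, lbl in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def walk(node: Node) -> list[int]:
        if node.is_leaf:
            return [index[node.label]]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        d[a, b] = d[b, a] = 2.0 * node.height
        return [x for g in groups for x in g]

    walk(tree.root)
    return DistanceMatrix(labels, d)
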