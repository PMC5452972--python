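"""Rooted phylogenies: balanced-tree generation and Newick round-tripping.

The package's benchmark trees are complete balanced binary trees in which
every edge (including the two edges below the root) has the same length ``b``,
so any two adjacent nodes are separated by the same divergence and a cherry
(two taxa) has pairwise divergence ``2b``. Branch lengths are in expected
substitutions per codon site under the neutral clock (see docs/methods.md).

Arbitrary user trees are supported through :meth:`PhyloTree.from_newick`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree", "make_balanced_tree"]


@dataclass
class PhyloTree:
    """A rooted tree stored in flat arrays for fast postorder traversal.

    Nodes are integers ``0..n_nodes-1``. ``children[i]`` lists the children of
    node ``i`` (empty for leaves); ``edge_length[i]`` is the length of the edge
    above node ``i`` (0 and unused for the root). ``labels[i]`` is the taxon
    label for leaves, ``None`` for internal nodes.
    """

    children: list[list[int]]
    edge_length: np.ndarray
    labels: list[str | None]
    root: int = 0
    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        non_root = [i for i in range(self.n_nodes) if i != self.root]
        if non_root and not np.all(self.edge_length[non_root] > 0):
            raise ValueError("all edge lengths must be strictly positive")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def leaf_ids(self) -> np.ndarray:
        return np.array([i for i, ch in enumerate(self.children) if not ch], dtype=np.intp)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_ids]

    @property
    def n_taxa(self) -> int:
        return len(self.leaf_ids)

    @property
    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children always before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=np.intp)
        return self._postorder

    def is_binary(self) -> bool:
        return all(len(ch) in (0, 2) for ch in self.children)

    # -- Newick ------------------------------------------------------------

    def to_newick(self) -> str:
        """Serialize to Newick with ``%.10g`` branch lengths."""

        out = io.StringIO()

        def write(node: int) -> None:
            ch = self.children[node]
            if ch:
                out.write("(")
                for k, c in enumerate(ch):
                    if k:
                        out.write(",")
                    write(c)
                out.write(")")
            else:
                out.write(self.labels[node])
            if node != self.root:
                out.write(":%.10g" % self.edge_length[node])

        write(self.root)
        out.write(";")
        return out.getvalue()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a rooted Newick string (branch lengths required on all edges)."""
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy errors carry the failure position
            raise ValueError(f"malformed Newick: {exc}") from exc

        children: list[list[int]] = []
        lengths: list[float] = []
        labels: list[str | None] = []

        def build(dnode) -> int:
            idx = len(children)
            children.append([])
            lengths.append(0.0)
            labels.append(None)
            kids = dnode.child_nodes()
            if kids:
                for k in kids:
                    cidx = build(k)
                    children[idx].append(cidx)
            else:
                labels[idx] = dnode.taxon.label if dnode.taxon else None
                if labels[idx] is None:
                    raise ValueError("malformed Newick: unlabeled leaf")
            return idx

        root = build(dtree.seed_node)
        # second pass for edge lengths (same traversal order)
        idx_iter = iter(range(len(children)))

        def lengths_pass(dnode) -> None:
            idx = next(idx_iter)
            if dnode.parent_node is not None:
                if dnode.edge.length is None:
                    raise ValueError("malformed Newick: missing branch length")
                lengths[idx] = float(dnode.edge.length)
            for k in dnode.child_nodes():
                lengths_pass(k)

        lengths_pass(dtree.seed_node)
        return cls(children=children, edge_length=np.array(lengths), labels=labels, root=root)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())


def make_balanced_tree(n_taxa: int, branch_length: float) -> PhyloTree:
    """Build a complete balanced binary tree with uniform edge lengths.

    Parameters
    ----------
    n_taxa
        Number of leaves; must be a power of two and >= 2.
    branch_length
        Length assigned to every edge, including the root's two child edges,
        so adjacent nodes are always ``branch_length`` apart and a cherry's
        two leaves are ``2 * branch_length`` apart.

    Returns
    -------
    PhyloTree
        Tree with ``2 * n_taxa - 2`` edges and leaves labelled ``t1..tn``
        left to right.
    """
    if n_taxa < 2 or n_taxa & (n_taxa - 1):
        raise ValueError(f"n_taxa must be a power of two >= 2, got {n_taxa}")
    if not branch_length > 0:
        raise ValueError(f"branch_length must be positive, got {branch_length}")

    children: list[list[int]] = [[]]
    lengths: list[float] = [0.0]
    labels: list[str | None] = [None]
    counter = iter(range(1, n_taxa + 1))

    def grow(node: int, n_below: int) -> None:
        if n_below == 1:
            labels[node] = f"t{next(counter)}"
            return
        for _ in range(2):
            idx = len(children)
            children.append([])
            lengths.append(float(branch_length))
            labels.append(None)
            children[node].append(idx)
        left, right = children[node]
        grow(left, n_below // 2)
        grow(right, n_below // 2)

    grow(0, n_taxa)
    return PhyloTree(children=children, edge_length=np.array(lengths), labels=labels)
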