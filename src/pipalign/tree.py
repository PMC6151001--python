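"""Rooted binary guide trees.

The guide tree orders the progressive merges and supplies every branch
length entering the indel-process quantities (insertion probabilities,
survival probabilities, total tree length).  Trees are strictly rooted
and binary: the dynamic program and the ancestral-set bookkeeping are
defined on that shape, so multifurcating or unrooted inputs are rejected
rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["Tree", "TreeError", "parse_newick", "to_newick"]


class TreeError(ValueError):
    """Raised for malformed or non-conforming guide trees."""


@dataclass
class Tree:
    """A rooted binary phylogeny stored as parallel node arrays.

    Nodes are integer indices ``0 .. 2N-2`` in postorder (children before
    parents, root last).  ``branch_length[v]`` is the length of the branch
    from ``v`` to its parent, in expected substitutions per site; the root
    has no branch (``parent[root] == -1`` and its length is 0.0 and unused:
    the root carries a virtual infinite stem instead).

    Attributes
    ----------
    parent : list[int]
        Parent index per node; -1 for the root.
    children : list[tuple[int, ...]]
        Child indices per node; empty tuple for leaves, pairs otherwise.
    branch_length : list[float]
        Branch length into each node (0.0 at the root, never used).
    labels : list[str | None]
        Taxon label per leaf node, None for internal nodes.
    """

    parent: list[int]
    children: list[tuple[int, ...]]
    branch_length: list[float]
    labels: list[str | None]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        self.root = len(self.parent) - 1
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = []
        children = []
        blen = []
        labels: list[str | None] = []
        for nd in nodes:
            kids = nd.child_nodes()
            if len(kids) not in (0, 2):
                raise TreeError(
                    f"non-binary node with {len(kids)} children "
                    f"(path: {_node_path(nd)}); only rooted binary trees are accepted"
                )
            par = nd.parent_node
            parent.append(index[id(par)] if par is not None else -1)
            children.append(tuple(index[id(k)] for k in kids))
            if par is None:
                blen.append(0.0)
            else:
                if nd.edge.length is None:
                    raise TreeError(
                        f"missing branch length on the edge into node at {_node_path(nd)}"
                    )
                blen.append(float(nd.edge.length))
            if kids:
                labels.append(None)
            else:
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("leaf without a taxon label")
                labels.append(nd.taxon.label)
        return cls(parent, children, blen, labels)

    def _validate(self) -> None:
        n_leaves = sum(1 for c in self.children if not c)
        if n_leaves < 2:
            raise TreeError("a guide tree needs at least 2 leaves")
        if len(self.parent) != 2 * n_leaves - 1:
            raise TreeError("node count inconsistent with a binary tree")
        seen: set[str] = set()
        for lab in self.labels:
            if lab is not None:
                if lab in seen:
                    raise TreeError(f"duplicate leaf label {lab!r}")
                seen.add(lab)
        for v, b in enumerate(self.branch_length):
            if v != self.root and not b > 0.0:
                raise TreeError(
                    f"branch length into node {v} must be strictly positive (got {b})"
                )
        # children must precede parents (postorder contract)
        for v, kids in enumerate(self.children):
            for k in kids:
                if k >= v:
                    raise TreeError("node order is not postorder")

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return (self.n_nodes + 1) // 2

    @property
    def leaves(self) -> list[int]:
        """Leaf indices in postorder."""
        return [v for v, c in enumerate(self.children) if not c]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[v] for v in self.leaves]  # type: ignore[misc]

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (the root stem excluded)."""
        return sum(b for v, b in enumerate(self.branch_length) if v != self.root)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def postorder(self) -> list[int]:
        """All node indices, children before parents, root last."""
        return list(range(self.n_nodes))

    def internal_postorder(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.children[v]]

    def subtree_nodes(self, v: int) -> list[int]:
        """Node indices of the clade rooted at ``v``, in postorder."""
        out: list[int] = []

        def walk(u: int) -> None:
            for k in self.children[u]:
                walk(k)
            out.append(u)

        walk(v)
        return out

    def subtree_leaf_labels(self, v: int) -> list[str]:
        return [self.labels[u] for u in self.subtree_nodes(v) if self.is_leaf(u)]

    def subtree_length(self, v: int) -> float:
        """Sum of branch lengths strictly below ``v`` (``v``'s own branch excluded)."""
        return sum(self.branch_length[u] for u in self.subtree_nodes(v) if u != v)

    def mrca(self, nodes: set[int]) -> int:
        """Most recent common ancestor of a non-empty node set."""
        if not nodes:
            raise ValueError("mrca of an empty set")
        paths = []
        for v in nodes:
            path = []
            u = v
            while u != -1:
                path.append(u)
                u = self.parent[u]
            paths.append(set(path))
        common = set.intersection(*paths)
        return min(common)  # postorder index: the deepest common ancestor is smallest


def _node_path(nd: dendropy.Node) -> str:
    parts = []
    while nd is not None:
        parts.append(nd.taxon.label if nd.taxon else "*")
        nd = nd.parent_node
    return "/".join(reversed(parts))


def parse_newick(text: str) -> Tree:
    """Parse a single newick statement into a validated rooted binary Tree.

    Internal-node labels and a root branch length are accepted and ignored;
    they enter no likelihood quantity.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed newick: {exc}") from exc
    return Tree.from_dendropy(dtree)


def to_newick(tree: Tree, precision: int = 12) -> str:
    """Serialize back to newick with the stored branch lengths."""

    def fmt(v: int) -> str:
        if tree.is_leaf(v):
            core = tree.labels[v]
        else:
            core = "(" + ",".join(fmt(k) for k in tree.children[v]) + ")"
        if v == tree.root:
            return core
        return f"{core}:{tree.branch_length[v]:.{precision}g}"

    return fmt(tree.root) + ";"
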