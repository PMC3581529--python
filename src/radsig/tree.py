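"""Rooted trees with branch lengths and internal-node supports.

Newick parsing is delegated to dendropy; supports are read from
internal-node labels (the dialect MEGA/PhyML emit). Unrooted newick
strings (basal trifurcation) are accepted and stored with a degree-3
root; operations elsewhere state their root handling explicitly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

from .core import RadsigError


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None  # branch length to parent; None on root
    support: Optional[float] = None  # percent in [0,100], internal nodes only
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """A rooted tree; the root may have degree 2 or 3 (unrooted style)."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise RadsigError("leaf labels are not unique")
        if any(lb is None for lb in labels):
            raise RadsigError("every leaf must be labelled")
        for n in self.postorder():
            if n is not self.root:
                if n.length is None or not math.isfinite(n.length) or n.length < 0:
                    raise RadsigError(
                        f"branch length missing/invalid on node {n.label!r}"
                    )
            if n.support is not None and not (0.0 <= n.support <= 100.0):
                raise RadsigError(
                    f"support {n.support} outside [0, 100] on an internal node"
                )

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            for c in n.children:
                yield from walk(c)
            yield n

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.length is not None)

    # -- splits ------------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set not containing the
        lexicographically smallest leaf (canonical orientation)."""
        all_leaves = set(self.leaf_labels())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = {n.label}  # type: ignore[arg-type]
            else:
                s: set[str] = set()
                for c in n.children:
                    s |= below[id(c)]
                below[id(n)] = s
                if n is self.root:
                    continue
                side = s if anchor not in s else all_leaves - s
                if len(side) >= 2 and len(all_leaves - side) >= 2:
                    splits.add(frozenset(side))
        return splits

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            m = Node(label=n.label, length=n.length, support=n.support)
            for c in n.children:
                m.add(clone(c))
            return m

        return Tree(clone(self.root))

    def __repr__(self) -> str:
        return f"<Tree with {self.n_leaves} leaves>"


# -- newick ----------------------------------------------------------------

def _from_dendropy(
    dtree: dendropy.Tree,
    support_dialect: str,
    allow_missing_lengths: bool,
    scale_unit_supports: bool,
) -> Tree:
    def convert(dnode) -> Node:
        is_leaf = len(dnode.child_nodes()) == 0
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length
        node = Node(label=label if is_leaf else None)
        if length is None:
            if dnode.parent_node is not None and not allow_missing_lengths:
                raise RadsigError("missing branch length in newick input")
            length = 0.0 if dnode.parent_node is not None else None
        node.length = length
        if not is_leaf and support_dialect == "internal_label" and label not in (None, ""):
            try:
                node.support = float(label)
            except ValueError:
                raise RadsigError(f"internal label {label!r} is not a numeric support")
        for c in dnode.child_nodes():
            node.add(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    tree = Tree(root)
    if scale_unit_supports:
        sups = [n.support for n in tree.internal_nodes() if n.support is not None]
        if sups and max(sups) <= 1.0:
            for n in tree.internal_nodes():
                if n.support is not None:
                    n.support *= 100.0
    return tree


def parse_newick(
    text: str,
    support_dialect: str = "internal_label",
    allow_missing_lengths: bool = False,
    scale_unit_supports: bool = False,
) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    ``support_dialect``: ``internal_label`` reads internal node labels as
    percent supports; ``none`` ignores them. Posterior probabilities in
    [0, 1] are rescaled to percent when ``scale_unit_supports`` is set.
    """
    if support_dialect not in ("internal_label", "none"):
        raise RadsigError(f"unknown support dialect {support_dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise RadsigError(f"invalid newick: {exc}") from exc
    return _from_dendropy(dtree, support_dialect, allow_missing_lengths, scale_unit_supports)


def read_newick(path, **kwargs) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), **kwargs)


def to_newick(tree: Tree, support_dialect: str = "internal_label") -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            body = n.label or ""
        else:
            body = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if support_dialect == "internal_label" and n.support is not None:
                body += format(n.support, "g")
        if n.length is not None:
            body += f":{n.length:.10g}"
        return body

    return fmt(tree.root) + ";"


def write_newick(tree: Tree, path, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, **kwargs) + "\n")
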