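"""Rooted trees with branch lengths: newick reading and tip pruning.

Parsing is delegated to dendropy; the in-memory representation is a minimal
node structure tailored to pruning-algorithm traversals.  Branch lengths
are required on every non-root edge; internal labels are kept but unused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy

__all__ = ["TreeError", "Node", "PhyloTree", "read_newick", "parse_newick", "prune_to"]


class TreeError(ValueError):
    pass


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None  # branch length above this node
    children: list = field(default_factory=list)
    parent: Optional["Node"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


class PhyloTree:
    """Rooted tree; tip labels unique; branch lengths >= 0 on non-root edges."""

    def __init__(self, root: Node) -> None:
        self.root = root
        labels = [t.label for t in self.tips()]
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels are not unique")
        if any(lbl is None for lbl in labels):
            raise TreeError("every tip must be labelled")
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(
                    f"missing branch length above {node.label or 'an internal node'}"
                )
            if node.length < 0:
                raise TreeError(f"negative branch length above {node.label!r}")

    # -- traversals -----------------------------------------------------------

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[Node]:
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def is_binary(self) -> bool:
        return all(
            len(n.children) in (0, 2) for n in self.preorder()
        )

    def root_to_tip_length(self, label: str) -> float:
        for tip in self.tips():
            if tip.label == label:
                total, node = 0.0, tip
                while node.parent is not None:
                    total += node.length
                    node = node.parent
                return total
        raise TreeError(f"no tip labelled {label!r}")

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.length is not None:
                core += f":{node.length:g}"
            return core

        return fmt(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        node = Node(
            label=dnode.taxon.label if dnode.taxon else dnode.label,
            length=dnode.edge.length,
        )
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string; errors carry dendropy's position diagnostics."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def prune_to(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict to ``keep`` tips, suppressing degree-2 nodes (lengths sum)."""
    keep = set(keep)
    missing = keep - set(tree.tip_labels())
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("pruning must retain at least 2 tips")

    def rebuild(node: Node) -> Optional[Node]:
        if node.is_tip:
            if node.label in keep:
                return Node(label=node.label, length=node.length)
            return None
        kept_children = [c for c in (rebuild(ch) for ch in node.children) if c]
        if not kept_children:
            return None
        if len(kept_children) == 1:  # suppress unifurcation
            child = kept_children[0]
            if node.length is not None and child.length is not None:
                child.length += node.length
            elif node.length is not None:
                child.length = node.length
            return child
        new = Node(label=node.label, length=node.length)
        for c in kept_children:
            new.add_child(c)
        return new

    new_root = rebuild(tree.root)
    assert new_root is not None
    new_root.parent = None
    new_root.length = None  # root edge length is not meaningful after pruning
    return PhyloTree(new_root)
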