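"""Rooted, possibly multifurcating labelled trees with Newick I/O.

Trees here are parsimony substrates only: branch lengths in the input are
accepted and discarded, child order is preserved, internal nodes may carry
clade labels (e.g. ``Hylinae``), and polytomies are kept as written.
Following the common Newick convention, underscores in labels stand for
spaces; the writer performs the reverse substitution, so write -> read is
the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import NewickParseError

__all__ = ["Node", "Phylogeny", "parse_newick", "write_newick"]


@dataclass
class Node:
    label: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """A rooted tree; leaves carry unique taxon labels."""

    root: Node

    def __post_init__(self):
        labels = self.leaf_labels()
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate leaf labels: {sorted(dupes)}")

    def postorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, label: str) -> Node:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def parents(self) -> dict[int, Node | None]:
        """Map id(node) -> parent node (None for the root)."""
        parent: dict[int, Node | None] = {id(self.root): None}
        for node in self.preorder():
            for child in node.children:
                parent[id(child)] = node
        return parent

    def node_keys(self) -> dict[int, str]:
        """Stable identifier per node: its label, else ``node<postorder idx>``."""
        keys: dict[int, str] = {}
        for i, node in enumerate(self.postorder()):
            keys[id(node)] = node.label if node.label else f"node{i}"
        return keys


_LABEL_FORBIDDEN = set("(),;:[]")


def _read_label(text: str, i: int) -> tuple[str | None, int]:
    j = i
    while j < len(text) and text[j] not in _LABEL_FORBIDDEN and not text[j].isspace():
        j += 1
    label = text[i:j]
    return (label.replace("_", " ") if label else None), j


def _skip_branch_length(text: str, i: int) -> int:
    if i < len(text) and text[i] == ":":
        i += 1
        j = i
        while j < len(text) and (text[j].isdigit() or text[j] in ".eE+-"):
            j += 1
        if j == i:
            raise NewickParseError(f"expected branch length after ':' at position {i}")
        return j
    return i


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string (polytomies and internal labels allowed)."""
    s = "".join(text.split())  # Newick whitespace is not significant
    if not s:
        raise NewickParseError("empty Newick string")
    if not s.endswith(";"):
        raise NewickParseError("Newick string must end with ';'")
    s = s[:-1]

    def parse_clade(i: int) -> tuple[Node, int]:
        node = Node()
        if i < len(s) and s[i] == "(":
            i += 1
            while True:
                child, i = parse_clade(i)
                node.children.append(child)
                if i >= len(s):
                    raise NewickParseError("unbalanced parentheses (unexpected end)")
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise NewickParseError(
                    f"unexpected character {s[i]!r} at position {i}"
                )
        node.label, i = _read_label(s, i)
        i = _skip_branch_length(s, i)
        return node, i

    root, i = parse_clade(0)
    if i != len(s):
        raise NewickParseError(
            f"trailing characters after tree at position {i}: {s[i:]!r}"
        )
    if root.is_leaf and root.label is None:
        raise NewickParseError("tree has no nodes")
    unlabelled = sum(
        1 for node in Phylogeny(root=root).postorder()
        if node.is_leaf and node.label is None
    )
    if unlabelled:
        raise NewickParseError(f"{unlabelled} leaf/leaves without a taxon label")
    return Phylogeny(root=root)


def write_newick(tree: Phylogeny) -> str:
    """Canonical Newick: preserved child order, no branch lengths."""

    def fmt(node: Node) -> str:
        label = (node.label or "").replace(" ", "_")
        if node.is_leaf:
            return label
        return "(" + ",".join(fmt(c) for c in node.children) + ")" + label

    return fmt(tree.root) + ";"
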