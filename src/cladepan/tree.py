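"""Minimal phylogenetic tree container with deterministic Newick output.

The writer sorts children by their smallest descendant leaf label and uses a
fixed branch-length format, so serializing the same tree twice is
byte-identical; the reader is the exact inverse, which makes round-trip tests
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .records import CladepanError


@dataclass
class TreeNode:
    """A node of a (rooted or unrooted) tree.

    Unrooted trees are stored rooted at an arbitrary internal node; all
    topology comparisons go through :func:`bipartitions`, which is invariant
    to that choice.
    """

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        names = []
        for leaf in self.leaves():
            if leaf.name is None:
                raise CladepanError("tree has an unlabeled leaf")
            names.append(leaf.name)
        return names

    def min_leaf(self) -> str:
        return min(self.leaf_names())

    def sort(self) -> None:
        """Sort children recursively by smallest descendant leaf label."""
        for node in self.walk():
            node.children.sort(key=lambda c: c.min_leaf())

    def copy(self) -> "TreeNode":
        return TreeNode(
            name=self.name,
            length=self.length,
            support=self.support,
            children=[c.copy() for c in self.children],
        )

    def find_leaf(self, name: str) -> "TreeNode":
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise CladepanError(f"no leaf named {name!r}")


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (effectively unrooted) tree.

    Each internal edge splits the leaves in two; the split is canonicalized
    as the frozenset of the side not containing the overall smallest label,
    so the result is invariant to rooting.
    """
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def below(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        clade = frozenset().union(*(below(c) for c in node.children))
        if 1 < len(clade) < len(all_leaves) - 1:
            side = clade if anchor not in clade else all_leaves - clade
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return clade

    below(tree)
    return splits


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Unweighted Robinson-Foulds distance (symmetric difference of splits)."""
    if sorted(a.leaf_names()) != sorted(b.leaf_names()):
        raise CladepanError("trees have different leaf sets")
    return len(bipartitions(a) ^ bipartitions(b))


def is_monophyletic(tree: TreeNode, labels: set[str]) -> bool:
    """True if `labels` form one side of an edge of the unrooted tree."""
    all_leaves = frozenset(tree.leaf_names())
    group = frozenset(labels)
    if not group <= all_leaves:
        raise CladepanError("labels not all present in tree")
    if len(group) <= 1 or len(all_leaves - group) <= 1:
        return True
    anchor = min(all_leaves)
    side = group if anchor not in group else all_leaves - group
    return side in bipartitions(tree)


def _format_length(x: float) -> str:
    s = f"{float(x):.6g}"
    if "." not in s and "e" not in s and "E" not in s:
        s += ".00000"
    return s


def to_newick(tree: TreeNode) -> str:
    """Serialize with sorted children, 6-significant-digit branch lengths and
    integer bootstrap supports as internal node labels."""
    tree = tree.copy()
    tree.sort()

    def render(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            if node.name is None:
                raise CladepanError("cannot write a tree with an unlabeled leaf")
            body = node.name
        else:
            inner = ",".join(render(c, False) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{_format_length(node.length)}"

    return render(tree, True) + ";"


def from_newick(text: str) -> TreeNode:
    """Parse the subset of Newick produced by :func:`to_newick`.

    Internal node labels that look like integers are read back as bootstrap
    supports; anything else becomes the node name.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise CladepanError("newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise CladepanError("unbalanced parentheses in newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.children and label.isdigit():
                node.support = int(label)
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise CladepanError(f"trailing characters in newick at offset {pos}")
    return root
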