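"""Rooted labelled trees.

A light node-based tree used throughout the package (pruning, reconciliation,
coalescent simulation all need fast traversal over many trees). Newick parsing
and serialisation go through dendropy at the file boundary; see
:mod:`avigc.io`.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Tip label (species id) for leaves; optional name for internal nodes.
    length : float or None
        Length of the branch subtending this node (absent for the root).
    support : float or None
        Support value attached to the node (read from internal-node labels).
    annotations : dict
        Free-form per-node metadata (trait values, time spans, thetas ...).
    """

    __slots__ = ("label", "length", "support", "children", "parent", "annotations")

    def __init__(self, label=None, length=None, support=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.annotations: dict = {}

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r})"


#: Recognised branch-length units. Never mixed within one tree.
UNITS = ("substitutions", "coalescent", "my", "none")


class LabeledTree:
    """Rooted tree with branch lengths in declared units.

    Parameters
    ----------
    root : TreeNode
    units : str
        One of ``substitutions``, ``coalescent``, ``my`` or ``none``.
    """

    def __init__(self, root: TreeNode, units: str = "none"):
        if units not in UNITS:
            raise ValueError(f"unknown branch-length units {units!r}")
        self.root = root
        self.units = units
        self._check_tips()

    def _check_tips(self):
        seen = set()
        for tip in self.tips():
            if tip.label is None:
                raise ValueError("tree has an unlabeled tip")
            if tip.label in seen:
                raise ValueError(f"duplicate tip label {tip.label!r}")
            seen.add(tip.label)

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> Iterator[TreeNode]:
        return (n for n in self.postorder() if n.is_leaf)

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def find(self, label: str) -> TreeNode:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(label)

    # -- editing -------------------------------------------------------
    def copy(self) -> "LabeledTree":
        def clone(node):
            new = TreeNode(node.label, node.length, node.support)
            new.annotations = dict(node.annotations)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return LabeledTree(clone(self.root), self.units)

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    # -- serialisation -------------------------------------------------
    def newick(self, support_as_label: bool = True) -> str:
        """Newick string; internal-node supports written as labels."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if support_as_label and node.support is not None:
                    s += format(node.support, "g")
                elif node.label:
                    s += node.label
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self):  # pragma: no cover
        return f"LabeledTree({self.n_tips} tips, units={self.units!r})"


def map_annotations(tree: LabeledTree, key: str, values: dict, by: str = "label"):
    """Attach ``values[label] -> node.annotations[key]`` over nodes with labels."""
    for node in tree.postorder():
        ident = getattr(node, by)
        if ident is not None and ident in values:
            node.annotations[key] = values[ident]


def tree_from_dendropy(dtree, units: str = "none",
                       support_from_labels: bool = True) -> LabeledTree:
    """Convert a dendropy Tree to a :class:`LabeledTree`."""

    def convert(dnode) -> TreeNode:
        is_leaf = not dnode.child_nodes()
        label = None
        support = None
        if is_leaf:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is not None:
                label = label.replace(" ", "_")
        else:
            raw = dnode.label
            if raw is not None and support_from_labels:
                try:
                    support = float(raw)
                except ValueError:
                    label = raw
            elif raw is not None:
                label = raw
        node = TreeNode(label=label, length=dnode.edge.length, support=support)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return LabeledTree(convert(dtree.seed_node), units=units)
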