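"""Rooted phylogenies with integer event-count branch lengths.

The package's trees are small (one leaf per tumour sample, typically 3-9
leaves plus a germline/diploid outgroup at the root), so the container is a
plain linked node structure.  Newick text is the interchange format; parsing
goes through dendropy so that quoting, comments and whitespace are handled
by a real grammar, while writing is a direct serialisation.

Topology enumeration (used by the exhaustive parsimony searches) represents
rooted binary shapes as nested tuples of leaf indices; ``tuples_to_tree``
converts a shape into a :class:`RootedTree`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "RootedTree",
    "rf_distance",
    "enumerate_rooted_topologies",
    "count_rooted_topologies",
    "tuples_to_tree",
]


class Node:
    """One node of a rooted tree.

    ``length`` is the branch length to the parent (an event count in this
    package; ``None`` for the root).  ``states`` optionally carries per-node
    ancestral character states.
    """

    __slots__ = ("name", "length", "children", "parent", "states")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.states: dict | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class RootedTree:
    """A rooted phylogeny with labelled leaves and event-count branch lengths."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # traversal helpers
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        names = set(names)
        if not names:
            raise ValueError("mrca of an empty leaf set is undefined")
        below: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name} & names
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if below[node] == names:
                return node
        raise ValueError(f"leaves {sorted(names)} not all present in tree")

    def path_length(self, ancestor: Node, descendant: Node) -> float:
        """Sum of branch lengths on the path from ``ancestor`` down to ``descendant``."""
        total = 0.0
        node = descendant
        while node is not ancestor:
            if node.parent is None:
                raise ValueError("ancestor is not on the root path of descendant")
            total += node.length or 0.0
            node = node.parent
        return total

    def copy(self) -> "RootedTree":
        def _copy(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.states = dict(node.states) if node.states else None
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return RootedTree(_copy(self.root))

    # ------------------------------------------------------------------
    # Newick round trip
    # ------------------------------------------------------------------
    def to_newick(self, lengths: bool = True) -> str:
        def _fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(_fmt(c) for c in node.children)
                label = f"({inner}){node.name or ''}"
            if lengths and node.length is not None:
                length = node.length
                if float(length).is_integer():
                    label += f":{int(length)}"
                else:
                    label += f":{length:g}"
            return label

        return _fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def _convert(dnode) -> Node:
            name = None
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            node = Node(name, dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(_convert(child))
            return node

        return cls(_convert(dtree.seed_node))

    # ------------------------------------------------------------------
    # bipartitions
    # ------------------------------------------------------------------
    def bipartitions(self, trivial: bool = False) -> set[frozenset]:
        """Unrooted splits, each as the canonical (reference-free) leaf side.

        The side not containing the lexicographically smallest leaf is used
        as the canonical representation, so the set is invariant under
        re-rooting.
        """
        all_names = frozenset(self.leaf_names())
        ref = min(all_names)
        splits: set[frozenset] = set()
        below: dict[Node, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            side = below[node]
            if ref in side:
                side = all_names - side
            if trivial or 1 < len(side) < len(all_names) - 1:
                splits.add(side)
        return splits


def rf_distance(a: RootedTree, b: RootedTree) -> int:
    """Robinson-Foulds distance (symmetric difference of unrooted splits).

    Computed over the shared leaf set; leaves private to one tree are
    ignored so an SNV tree can be compared with a CNA tree built from a
    subset of samples.
    """
    common = set(a.leaf_names()) & set(b.leaf_names())
    if len(common) < 3:
        raise ValueError("trees share fewer than 3 leaves; RF distance undefined")

    def restricted(tree: RootedTree) -> set[frozenset]:
        ref = min(common)
        n = len(common)
        splits = set()
        for side in tree.bipartitions(trivial=True):
            side = frozenset(side & common)
            if ref in side:
                side = frozenset(common - side)
            if 1 < len(side) < n - 1:
                splits.add(side)
        return splits

    return len(restricted(a) ^ restricted(b))


# ----------------------------------------------------------------------
# topology enumeration (nested-tuple shapes)
# ----------------------------------------------------------------------
def count_rooted_topologies(n: int) -> int:
    """Number of rooted binary tree shapes on ``n`` labelled leaves: (2n-3)!!."""
    if n < 1:
        raise ValueError("need at least one leaf")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def _insert_leaf(shape, leaf):
    """Yield every shape obtained by attaching ``leaf`` on an edge of ``shape``
    or above the current root."""
    yield (shape, leaf)
    if isinstance(shape, tuple):
        left, right = shape
        for new_left in _insert_leaf(left, leaf):
            yield (new_left, right)
        for new_right in _insert_leaf(right, leaf):
            yield (left, new_right)


def enumerate_rooted_topologies(labels: Sequence) -> Iterator:
    """All rooted binary tree shapes over ``labels`` as nested 2-tuples."""
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    shapes = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        shapes = [s for shape in shapes for s in _insert_leaf(shape, leaf)]
    yield from shapes


def tuples_to_tree(
    shape,
    outgroup: str | None = None,
    name_of: Callable[[object], str] = str,
) -> RootedTree:
    """Convert a nested-tuple shape into a :class:`RootedTree`.

    If ``outgroup`` is given, the shape becomes the cancer clade and the
    outgroup is attached as a sibling under a new root.
    """

    def _build(sub) -> Node:
        if isinstance(sub, tuple):
            node = Node()
            for part in sub:
                node.add_child(_build(part))
            return node
        return Node(name_of(sub))

    cancer = _build(shape)
    if outgroup is None:
        return RootedTree(cancer)
    root = Node()
    root.add_child(Node(outgroup))
    root.add_child(cancer)
    return RootedTree(root)
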