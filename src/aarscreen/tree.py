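"""Light unrooted-tree container: Newick IO, bipartitions, Robinson-Foulds.

The tree objects produced by neighbor joining and consumed by the bootstrap,
clade-assignment and congruence code are deliberately small: a rooted node
structure standing in for an unrooted tree (the root is an arbitrary
trifurcation), plus canonical bipartition sets for topology comparison.
"""

from __future__ import annotations

import io
import itertools
from typing import Iterable, Optional


class Node:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = length
        self.support: Optional[float] = None
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Tree:
    """Unrooted tree with leaf labels, branch lengths and edge supports."""

    def __init__(self, root: Node):
        self.root = root

    # ---------------- traversal ----------------

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[Node]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    # ---------------- topology ----------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical non-trivial bipartitions (internal edges only).

        Each internal edge is represented by the side *not* containing the
        lexicographically smallest leaf, as a frozenset of leaf labels.
        Trivial splits (single leaf / all-but-one) are excluded.
        """
        labels = sorted(self.leaf_labels())
        return _canonical_bipartitions(self._raw_sides(), set(labels))

    def _raw_sides(self) -> list[set[str]]:
        sides = []
        below: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label}
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= below[id(c)]
                below[id(node)] = s
                if node.parent is not None:
                    sides.append(s)
        return sides

    # ---------------- metrics ----------------

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        anc_a = self._ancestor_chain(a)
        anc_b = self._ancestor_chain(b)
        seen = {id(n): d for n, d in anc_a}
        for node, dist_b in anc_b:
            if id(node) in seen:
                return seen[id(node)] + dist_b
        raise ValueError(f"no path between {a!r} and {b!r}")

    def _ancestor_chain(self, label: str) -> list[tuple[Node, float]]:
        node = next((n for n in self.preorder() if n.is_leaf and n.label == label), None)
        if node is None:
            raise KeyError(f"leaf {label!r} not in tree")
        chain = []
        dist = 0.0
        while node is not None:
            chain.append((node, dist))
            dist += node.length
            node = node.parent
        return chain

    # ---------------- Newick ----------------

    def to_newick(self, support_as_label: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{_quote(node.label)}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            lab = ""
            if support_as_label and node.support is not None:
                lab = f"{node.support:g}"
            elif node.label:
                lab = _quote(node.label)
            if node.parent is None:
                return f"({inner}){lab}"
            return f"({inner}){lab}:{node.length:.6g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string (dendropy does the tokenising)."""
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
        return cls(_from_dendropy(dtree.seed_node))

    def copy(self) -> "Tree":
        return Tree.from_newick(self.to_newick(support_as_label=False))


def _quote(label: Optional[str]) -> str:
    if label is None:
        return ""
    if any(c in label for c in "()[]{}:;, '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length or 0.0)
    if dnode.label is not None and dnode.child_nodes():
        try:
            node.support = float(dnode.label)
            node.label = None
        except ValueError:
            pass
    for c in dnode.child_nodes():
        node.add(_from_dendropy(c))
    return node


# ---------------- bipartition utilities ----------------

def _canonical_bipartitions(sides: Iterable[set[str]],
                            universe: set[str]) -> set[frozenset[str]]:
    ref = min(universe)
    n = len(universe)
    out: set[frozenset[str]] = set()
    for side in sides:
        if ref in side:
            side = universe - side
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return out


def restrict_bipartitions(biparts: Iterable[frozenset[str]],
                          universe: set[str],
                          subset: set[str]) -> set[frozenset[str]]:
    """Restrict bipartitions to a leaf subset (prune-and-collapse semantics)."""
    sides = [set(b) & subset for b in biparts]
    return _canonical_bipartitions(sides, subset)


def robinson_foulds(a: "Tree", b: "Tree") -> int:
    """RF distance on the shared-leaf restriction of two trees."""
    la, lb = set(a.leaf_labels()), set(b.leaf_labels())
    shared = la & lb
    if len(shared) < 4:
        raise ValueError("trees share fewer than 4 leaves")
    ba = restrict_bipartitions(a.bipartitions(), la, shared)
    bb = restrict_bipartitions(b.bipartitions(), lb, shared)
    return len(ba ^ bb)


def random_topology(labels: list[str], rng) -> "Tree":
    """Uniform-ish random binary unrooted topology (sequential edge attach)."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 leaves")
    root = Node()
    for lab in labels[:3]:
        root.add(Node(lab, 1.0))
    tree = Tree(root)
    for lab in labels[3:]:
        edges = [n for n in tree.preorder() if n.parent is not None]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node(length=max(target.length / 2, 1e-9))
        target.length = max(target.length / 2, 1e-9)
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(lab, 1.0))
    return tree
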