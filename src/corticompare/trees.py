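"""Minimal phylogenetic tree structure with Newick I/O.

Trees are rooted in representation (a Node with children) but compared as
unrooted objects: topology comparison uses the set of non-trivial leaf
bipartitions, so a root-trifurcating tree and any rooting of the same
unrooted tree are equal under Robinson-Foulds distance.
"""

from __future__ import annotations

import itertools
from collections import deque

__all__ = [
    "Node",
    "parse_newick",
    "to_newick",
    "bipartitions",
    "robinson_foulds",
    "leaf_path_lengths",
]


class Node:
    """Tree node; ``length`` is the branch length of the edge above it."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []

    def add(self, child: "Node", length: float | None = None) -> "Node":
        if length is not None:
            child.length = length
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {to_newick(self)}>"


def parse_newick(text: str) -> Node:
    """Parse a Newick string (names and optional ':' branch lengths)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg):
        raise ValueError(f"malformed Newick at position {pos}: {msg}")

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                if child.is_leaf and child.name is None:
                    error("leaf without a name")
                node.children.append(child)
                if pos >= len(s):
                    error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
        # optional label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            node.name = label
        # optional branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}")
        return node

    root = parse_clade()
    if pos != len(s):
        error("trailing characters")
    if not root.children and root.name is None:
        error("empty tree")
    return root


def to_newick(node: Node, decimals: int = 6) -> str:
    """Serialize with branch lengths at fixed precision, ending in ';'."""

    def fmt(n: Node) -> str:
        if n.is_leaf:
            if not n.name:
                raise ValueError("unlabeled leaf cannot be serialized")
            s = n.name
        else:
            s = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.name:
                s += n.name
        if n.length is not None:
            s += f":{n.length:.{decimals}f}"
        return s

    return fmt(node) + ";"


def bipartitions(root: Node) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions of the unrooted topology.

    Each internal edge splits the leaves in two; the split is represented by
    the side that does not contain the lexicographically smallest leaf, so
    the representation is independent of rooting.
    """
    all_leaves = frozenset(root.leaf_names())
    if len(all_leaves) != len(root.leaf_names()):
        raise ValueError("duplicate leaf names")
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def clade(n: Node) -> frozenset[str]:
        if n.is_leaf:
            return frozenset([n.name])
        below = frozenset(itertools.chain.from_iterable(clade(c) for c in n.children))
        if 2 <= len(below) <= len(all_leaves) - 2:
            side = below if anchor not in below else all_leaves - below
            splits.add(side)
        return below

    clade(root)
    return splits


def robinson_foulds(tree_a: Node, tree_b: Node) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    la, lb = frozenset(tree_a.leaf_names()), frozenset(tree_b.leaf_names())
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


def leaf_path_lengths(root: Node) -> dict[tuple[str, str], float]:
    """Pairwise leaf-to-leaf path lengths, keyed by sorted name pairs."""
    # undirected adjacency over node objects
    adj: dict[int, list[tuple[Node, float]]] = {}
    nodes: dict[int, Node] = {}

    def walk(n: Node):
        nodes[id(n)] = n
        adj.setdefault(id(n), [])
        for c in n.children:
            if c.length is None:
                raise ValueError("path lengths need branch lengths on every edge")
            adj.setdefault(id(c), [])
            adj[id(n)].append((c, c.length))
            adj[id(c)].append((n, c.length))
            walk(c)

    walk(root)
    leaves = root.leaves()
    out: dict[tuple[str, str], float] = {}
    for leaf in leaves:
        dist = {id(leaf): 0.0}
        dq = deque([leaf])
        while dq:
            cur = dq.popleft()
            for nb, w in adj[id(cur)]:
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(cur)] + w
                    dq.append(nb)
        for other in leaves:
            if other.name == leaf.name:
                continue
            key = tuple(sorted((leaf.name, other.name)))
            out[key] = dist[id(other)]
    return out
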