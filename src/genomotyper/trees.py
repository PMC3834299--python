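"""Minimal rooted/unrooted tree structure with Newick serialization.

Trees are built from :class:`Node` objects.  A neighbour-joining result is
represented with a trifurcating root (the standard unrooted convention);
bipartitions are extracted per internal edge and canonicalized so that the
side *not* containing the alphabetically first leaf is kept.  This keeps
bipartition sets comparable across trees over the same leaf set regardless
of where the root sits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # branch length to the parent; None = omit
    support: float | None = None  # bootstrap support in [0, 100]
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]


def _fmt_length(length: float) -> str:
    return format(float(length), ".10g")


def _fmt_support(support: float) -> str:
    s = float(support)
    return format(s, ".10g") if s != int(s) else str(int(s))


def to_newick(root: Node) -> str:
    """Serialize a tree to a Newick string (deterministic, child order kept).

    Bootstrap supports, when set, appear as internal-node labels — the
    convention understood by ape, dendropy and most tree viewers.
    """

    def rec(node: Node) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.support is not None:
                s += _fmt_support(node.support)
            elif node.name:
                s += node.name
        if node.length is not None:
            s += ":" + _fmt_length(node.length)
        return s

    return rec(root) + ";"


def leaf_distances(root: Node) -> dict[tuple[str, str], float]:
    """Pairwise path lengths between all leaves (missing lengths count as 0)."""
    dist: dict[tuple[str, str], float] = {}

    def rec(node: Node) -> list[tuple[str, float]]:
        if node.is_leaf:
            below = [(node.name, 0.0)]
        else:
            groups = [rec(c) for c in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a, da in groups[i]:
                        for b, db in groups[j]:
                            key = (a, b) if a < b else (b, a)
                            dist[key] = da + db
            below = [pair for g in groups for pair in g]
        edge = node.length or 0.0
        return [(name, d + edge) for name, d in below]

    rec(root)
    return dist


def bipartitions(root: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted tree, one per internal edge.

    Each is returned as the frozenset of leaf names on the side *not*
    containing the alphabetically first leaf.  Trivial splits (single leaf
    or its complement) are excluded.
    """
    leaves = root.leaf_names()
    all_set = frozenset(leaves)
    anchor = min(leaves)
    out: set[frozenset[str]] = set()

    def rec(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(rec(c) for c in node.children))
        if node is not root:
            side = below if anchor not in below else all_set - below
            if 1 < len(side) < len(all_set) - 1:
                out.add(side)
        return below

    rec(root)
    return out


def annotate_supports(root: Node, supports: dict[frozenset[str], float]) -> None:
    """Attach bootstrap supports (percent) to the internal nodes of a tree.

    The support painted on each internal node is the one of the bipartition
    induced by the edge above it; canonicalization matches
    :func:`bipartitions`.
    """
    leaves = root.leaf_names()
    all_set = frozenset(leaves)
    anchor = min(leaves)

    def rec(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(rec(c) for c in node.children))
        if node is not root:
            side = below if anchor not in below else all_set - below
            if 1 < len(side) < len(all_set) - 1 and side in supports:
                node.support = supports[side]
        return below

    rec(root)
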