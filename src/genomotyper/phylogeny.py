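"""Binary-content distances, neighbour joining, and bootstrap consensus.

The strain dendrogram is built from the binary presence/absence matrix:
pairwise distances are mismatch proportions (Hamming; Jaccard optional),
trees come from the classical Saitou–Nei neighbour-joining agglomeration,
and supports from resampling genes (matrix columns are strains, rows are
genes; each bootstrap replicate resamples rows with replacement).  The
returned consensus is strict-majority (>50%) with bipartition supports in
percent; the full-data NJ tree with supports painted on its edges is kept
alongside, since either presentation may be wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import PresenceMatrix
from .errors import ConfigError
from .trees import Node, annotate_supports, bipartitions

_METRICS = ("hamming", "jaccard")


@dataclass
class DistanceMatrix:
    """Symmetric strain-by-strain mismatch proportions with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def validate(self) -> None:
        D = self.values
        if D.shape != (len(self.ids), len(self.ids)):
            raise ConfigError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(D)):
            raise ConfigError("distance matrix has non-finite entries")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ConfigError("distance matrix is not symmetric")
        if np.any(np.diag(D) != 0):
            raise ConfigError("distance matrix diagonal is not zero")
        if np.any(D < 0):
            raise ConfigError("distance matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def binary_distance(P, metric: str = "hamming",
                    strains: list[str] | None = None) -> DistanceMatrix:
    """Pairwise mismatch proportion between strain presence columns.

    ``P`` may be a :class:`PresenceMatrix` or a plain (genes x strains)
    0/1 array accompanied by ``strains``.
    """
    if metric not in _METRICS:
        raise ConfigError(f"unknown metric {metric!r}")
    if isinstance(P, PresenceMatrix):
        M, ids = P.P, list(P.strains)
    else:
        M = np.asarray(P)
        ids = list(strains) if strains is not None else \
            [f"t{i}" for i in range(M.shape[1])]
    G, S = M.shape
    if G == 0:
        raise ConfigError("no genes: cannot compute distances")
    if S < 3:
        raise ConfigError("need >=3 strains for a tree-ready distance matrix")
    B = M.astype(bool)
    inter = B.T.astype(np.int64) @ B.astype(np.int64)
    ones = B.sum(axis=0).astype(np.int64)
    mismatches = ones[:, None] + ones[None, :] - 2 * inter
    if metric == "hamming":
        D = mismatches / G
    else:
        union = ones[:, None] + ones[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(union > 0, mismatches / union, 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ids, D.astype(float))


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Classical Saitou–Nei neighbour joining.

    Q(i,j) = (n-2) D(i,j) - R_i - R_j; the Q-minimizing pair is joined, with
    ties broken by the lexicographically smallest (sorted) pair of node ids
    so the result is invariant to input order.  Branch lengths use the
    standard formulas; negatives are clamped to 0 with a warning.  On an
    additive matrix the output path lengths reproduce D exactly.  The
    returned root is the standard trifurcation (unrooted convention).
    """
    dm.validate()
    n0 = len(dm.ids)
    if n0 < 3:
        raise ConfigError("neighbour joining needs >=3 taxa")

    nodes: dict[str, Node] = {name: Node(name=name) for name in dm.ids}
    D: dict[frozenset, float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            D[frozenset((dm.ids[i], dm.ids[j]))] = float(dm.values[i, j])
    active = sorted(dm.ids)
    clamped = False

    def dist(a: str, b: str) -> float:
        return D[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        R = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best, best_pair = None, None
        for ia in range(n):
            for ib in range(ia + 1, n):
                a, b = active[ia], active[ib]
                q = (n - 2) * dist(a, b) - R[a] - R[b]
                if best is None or q < best - 1e-12:
                    best, best_pair = q, (a, b)
        a, b = best_pair
        d_ab = dist(a, b)
        va = 0.5 * d_ab + (R[a] - R[b]) / (2 * (n - 2))
        vb = d_ab - va
        if va < 0 or vb < 0:
            clamped = True
            va, vb = max(va, 0.0), max(vb, 0.0)
        new_id = min(a, b)  # deterministic internal id for tie-breaking
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = va, vb
        u = Node(children=[child_a, child_b])
        new_d = {k: 0.5 * (dist(a, k) + dist(b, k) - d_ab)
                 for k in active if k not in (a, b)}
        active = sorted([k for k in active if k not in (a, b)] + [new_id])
        for k, v in new_d.items():
            D[frozenset((new_id, k))] = v
        nodes[new_id] = u

    a, b, c = active
    va = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    vb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    vc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    if min(va, vb, vc) < 0:
        clamped = True
        va, vb, vc = max(va, 0.0), max(vb, 0.0), max(vc, 0.0)
    for name, v in zip((a, b, c), (va, vb, vc)):
        nodes[name].length = v
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return root


@dataclass
class SupportTree:
    """Consensus dendrogram with bipartition bootstrap supports (percent)."""

    tree: Node                          # majority-rule consensus
    full_tree: Node | None              # full-data NJ tree, supports painted on
    supports: dict[frozenset, float]    # bipartition -> percent of replicates
    n_replicates: int
    seed: int | None = None

    def support_table(self) -> pd.DataFrame:
        rows = [{"bipartition": "|".join(sorted(k)), "support_pct": v}
                for k, v in sorted(self.supports.items(),
                                   key=lambda kv: (-kv[1], "|".join(sorted(kv[0]))))]
        return pd.DataFrame(rows, columns=["bipartition", "support_pct"])


def _majority_consensus(leaves: list[str], supports: dict[frozenset, float]) -> Node:
    """Build the strict-majority (>50%) consensus tree from clade supports.

    Bipartition sides are canonicalized to exclude the alphabetically first
    leaf, so majority sides form a laminar family of clades rooted away
    from that anchor.
    """
    majority = {c: s for c, s in supports.items() if s > 50.0}
    full = frozenset(leaves)
    clades = sorted(majority, key=lambda c: (-len(c), "|".join(sorted(c))))
    parent: dict[frozenset, frozenset] = {}
    placed: list[frozenset] = [full]
    for c in clades:
        containers = [e for e in placed if c < e]
        parent[c] = min(containers, key=len)
        placed.append(c)

    node_of: dict[frozenset, Node] = {full: Node()}
    for c in clades:
        node_of[c] = Node(support=majority[c])
    for c in clades:
        node_of[parent[c]].children.append(node_of[c])
    for leaf in sorted(leaves):
        candidates = [c for c in placed if leaf in c]
        host = min(candidates, key=len)
        node_of[host].children.append(Node(name=leaf))
    return node_of[full]


def bootstrap_consensus(P, B: int = 1000, seed: int | None = None,
                        metric: str = "hamming",
                        strains: list[str] | None = None) -> SupportTree:
    """Gene-resampling bootstrap of the NJ tree with majority-rule consensus.

    Each of the ``B`` replicates resamples the genes (rows) with
    replacement, recomputes the distance matrix and the NJ tree, and
    accumulates bipartition frequencies.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ConfigError("bootstrap replicate count must be >= 1")
    if isinstance(P, PresenceMatrix):
        M, ids = P.P, list(P.strains)
    else:
        M = np.asarray(P)
        ids = list(strains) if strains is not None else \
            [f"t{i}" for i in range(M.shape[1])]
    G = M.shape[0]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(B):
        idx = rng.integers(0, G, size=G)
        dm = binary_distance(M[idx], metric=metric, strains=ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = neighbor_joining(dm)
        for bip in bipartitions(tree):
            counts[bip] = counts.get(bip, 0) + 1
    supports = {bip: 100.0 * c / B for bip, c in counts.items()}

    consensus = _majority_consensus(ids, supports)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_tree = neighbor_joining(binary_distance(M, metric=metric, strains=ids))
    annotate_supports(full_tree, supports)
    return SupportTree(tree=consensus, full_tree=full_tree, supports=supports,
                       n_replicates=B, seed=seed)
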