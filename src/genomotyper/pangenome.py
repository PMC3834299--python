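"""Core/variable/reference-specific partition and gene-content overlap statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import PresenceMatrix
from .errors import ConfigError


@dataclass
class PanGenomePartition:
    """Partition of kept probes into core / variable / reference-specific sets.

    ``core`` is the intersection over the conspecific strain scope (outgroups
    excluded by default); ``reference_specific`` genes hybridize only in the
    reference, absent from every other strain including hybridized outgroups.
    ``overlap`` is the symmetric matrix O(s,t) = #genes present in both; the
    dissimilarity d(s) is the percentage of reference-present genes absent in
    s, and satisfies d(s) = 100 * (1 - O(ref,s)/O(ref,ref)).
    """

    core_genes: list[str]
    variable_genes: list[str]
    reference_specific: list[str]
    present_counts: dict[str, int]
    overlap: pd.DataFrame
    dissimilarity_pct: pd.Series
    scope: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_core": len(self.core_genes),
            "n_variable": len(self.variable_genes),
            "n_reference_specific": len(self.reference_specific),
            "present_counts": dict(self.present_counts),
            "dissimilarity_pct": {k: float(v) for k, v in self.dissimilarity_pct.items()},
            "scope": list(self.scope),
        }


def pairwise_overlaps(P: PresenceMatrix) -> pd.DataFrame:
    """O(s,t) = number of genes present in both strains (O = P^T P)."""
    M = P.P.astype(np.int64)
    O = M.T @ M
    return pd.DataFrame(O, index=P.strains, columns=P.strains)


def dissimilarity_vs_reference(P: PresenceMatrix) -> pd.Series:
    """d(s) = % of reference-present genes with P=0 in strain s."""
    if P.reference is None or P.reference not in P.strains:
        raise ConfigError("presence matrix has no reference column")
    ref = P.column(P.reference).astype(bool)
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ConfigError("reference strain has zero present genes")
    out = {}
    for s in P.strains:
        missing = int((ref & (P.column(s) == 0)).sum())
        out[s] = 100.0 * missing / n_ref
    return pd.Series(out, name="dissimilarity_pct")


def partition(P: PresenceMatrix, scope: list[str] | None = None,
              require_absent_in_outgroups: bool = True) -> PanGenomePartition:
    """Partition kept probes into core / variable / reference-specific sets.

    ``scope`` defaults to the conspecific strains (reference plus tests,
    outgroups excluded): the core is their column-wise intersection.
    Reference-specific genes must additionally be absent in hybridized
    outgroups unless ``require_absent_in_outgroups`` is off.
    """
    if scope is None:
        scope = [s for s in P.strains if s not in P.outgroups]
    if not scope:
        raise ConfigError("empty strain scope")
    missing = [s for s in scope if s not in P.strains]
    if missing:
        raise ConfigError(f"scope strains not in presence matrix: {missing}")

    scope_idx = [P.strains.index(s) for s in scope]
    core_mask = P.P[:, scope_idx].all(axis=1)
    core = [g for g, m in zip(P.probe_ids, core_mask) if m]
    variable = [g for g, m in zip(P.probe_ids, core_mask) if not m]

    ref_specific: list[str] = []
    if P.reference is not None and P.reference in P.strains:
        others = [s for s in P.strains if s != P.reference]
        if not require_absent_in_outgroups:
            others = [s for s in others if s not in P.outgroups]
        other_idx = [P.strains.index(s) for s in others]
        refcol = P.column(P.reference).astype(bool)
        mask = refcol & (P.P[:, other_idx] == 0).all(axis=1) if other_idx else refcol
        ref_specific = [g for g, m in zip(P.probe_ids, mask) if m]

    overlap = pairwise_overlaps(P)
    dis = dissimilarity_vs_reference(P) if P.reference in (P.strains or []) else \
        pd.Series(dtype=float)

    # internal consistency: d(s) = 100 * (1 - O(ref,s)/O(ref,ref))
    if len(dis):
        alt = 100.0 * (1 - overlap.loc[P.reference] / overlap.loc[P.reference, P.reference])
        if not np.allclose(dis.to_numpy(), alt.to_numpy(), atol=1e-9):
            raise AssertionError("dissimilarity/overlap consistency identity violated")

    return PanGenomePartition(
        core_genes=core, variable_genes=variable, reference_specific=ref_specific,
        present_counts=P.present_counts(), overlap=overlap,
        dissimilarity_pct=dis, scope=list(scope))
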