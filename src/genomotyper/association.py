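"""Presence/absence trait association with one-mismatch tolerance.

A gene is associated with a two-group phenotype when it is present in the
phenotype-positive group (A) and absent from the negative group (B).  The
strict set-algebraic criterion is relaxed to tolerate one false negative
(an A strain without the gene) *or* one false positive (a B strain with
it) — exclusive by default, i.e. fn + fp <= 1 — with both caps exposed so
the one-of-each reading is also available.

Only the A-present direction is searched: every probe derives from the
reference genome (an A-group member for both phenotypes studied), so genes
private to the B group are unobservable on this array design.  The
reference strain and outgroup taxa are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrayio import TraitTable
from .calling import PresenceMatrix
from .errors import ConfigError

_CLASS_ORDER = {"perfect": 0, "one_fn": 1, "one_fp": 2, "relaxed": 3}


@dataclass(frozen=True)
class AssociationRule:
    """Mismatch tolerance: accept iff fn<=max_fn, fp<=max_fp, fn+fp<=max_total."""

    max_fn: int = 1
    max_fp: int = 1
    max_total: int = 1

    def accepts(self, fn: int, fp: int) -> bool:
        return fn <= self.max_fn and fp <= self.max_fp and fn + fp <= self.max_total


@dataclass
class TraitHit:
    gene_id: str
    n_A_present: int
    n_A_total: int
    n_B_absent: int
    n_B_total: int

    @property
    def fn(self) -> int:
        return self.n_A_total - self.n_A_present

    @property
    def fp(self) -> int:
        return self.n_B_total - self.n_B_absent

    @property
    def match_class(self) -> str:
        if self.fn == 0 and self.fp == 0:
            return "perfect"
        if self.fn == 1 and self.fp == 0:
            return "one_fn"
        if self.fn == 0 and self.fp == 1:
            return "one_fp"
        return "relaxed"


def associate(P: PresenceMatrix, traits: TraitTable,
              rule: AssociationRule = AssociationRule(),
              exclude: list[str] | None = None) -> list[TraitHit]:
    """Genes present in group A and absent in group B, up to the rule's tolerance.

    The reference strain and outgroups are always excluded from scoring (on
    top of any ``exclude`` list and strains labelled 'excluded' in the trait
    table).  Hits are sorted by (match class, gene id).
    """
    excluded = set(exclude or [])
    if P.reference:
        excluded.add(P.reference)
    excluded.update(P.outgroups)

    missing = [s for s, lab in traits.labels.items()
               if lab in ("A", "B") and s not in excluded and s not in P.strains]
    if missing:
        raise ConfigError(f"trait strains missing from presence matrix: {missing}")

    group_a = [s for s in traits.group("A") if s not in excluded]
    group_b = [s for s in traits.group("B") if s not in excluded]
    if not group_a or not group_b:
        raise ConfigError(
            f"empty phenotype group after exclusions (A={len(group_a)}, B={len(group_b)})")

    a_idx = [P.strains.index(s) for s in group_a]
    b_idx = [P.strains.index(s) for s in group_b]
    A = P.P[:, a_idx].astype(bool)
    Bm = P.P[:, b_idx].astype(bool)
    n_a_present = A.sum(axis=1)
    n_b_absent = (~Bm).sum(axis=1)
    fn = len(a_idx) - n_a_present
    fp = len(b_idx) - n_b_absent

    hits = [TraitHit(g, int(nap), len(a_idx), int(nba), len(b_idx))
            for g, nap, nba, f_n, f_p in
            zip(P.probe_ids, n_a_present, n_b_absent, fn, fp)
            if rule.accepts(int(f_n), int(f_p))]
    hits.sort(key=lambda h: (_CLASS_ORDER.get(h.match_class, 9), h.gene_id))
    return hits


def hits_to_frame(hits: list[TraitHit]) -> pd.DataFrame:
    rows = [{"gene_id": h.gene_id, "match_class": h.match_class,
             "n_A_present": h.n_A_present, "n_A_total": h.n_A_total,
             "n_B_absent": h.n_B_absent, "n_B_total": h.n_B_total,
             "fn": h.fn, "fp": h.fp} for h in hits]
    return pd.DataFrame(rows, columns=["gene_id", "match_class", "n_A_present",
                                       "n_A_total", "n_B_absent", "n_B_total",
                                       "fn", "fp"])


@dataclass
class RecoveryResult:
    """End-to-end planted-trait recovery score."""

    hits: list[TraitHit]
    planted: list[str]
    recovered: list[str]
    false_hits: list[str]
    truth_matched: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return len(self.recovered) / len(self.planted) if self.planted else float("nan")

    @property
    def n_false_hits(self) -> int:
        return len(self.false_hits)


def truth_matching_genes(truth, traits: TraitTable,
                         rule: AssociationRule = AssociationRule()) -> list[str]:
    """Genes whose *true* content pattern matches the split (diverged counts
    as absent) — the expected hit set if calling were error-free."""
    strains_a = [s for s in traits.group("A") if s in truth.strains]
    strains_b = [s for s in traits.group("B") if s in truth.strains]
    pres = truth.presence_bool()
    a_idx = [truth.strains.index(s) for s in strains_a]
    b_idx = [truth.strains.index(s) for s in strains_b]
    fn = len(a_idx) - pres[:, a_idx].sum(axis=1)
    fp = pres[:, b_idx].sum(axis=1)
    return [g for g, f_n, f_p in zip(truth.gene_ids, fn, fp)
            if rule.accepts(int(f_n), int(f_p))]


def recover_planted_traits(truth, arrays, traits: TraitTable | None = None,
                           rule: AssociationRule = AssociationRule(),
                           cutoff: float = 0.95, background_k: float = 3.0,
                           anova_policy: str = "none") -> RecoveryResult:
    """Run preprocess -> presence calling -> association and score against truth.

    ``truth``/``arrays`` come from :mod:`genomotyper.simulate`; the trait
    table defaults to the simulator's planted grouping.  False hits are
    called hits that were not planted; genes whose random loss pattern
    genuinely matches the split are reported separately via
    ``truth_matched`` so they can be discounted.
    """
    from .calling import call_presence, fit_all_strains
    from .preprocess import (anova_probe_filter, average_replicates,
                             filter_selfself_background)
    from .simulate import trait_table_from_config  # noqa: F401 (doc pointer)

    if traits is None:
        groups = {}
        for s in truth.strains:
            if s == truth.reference or s in truth.outgroups:
                continue
            groups[s] = "A"
        # planted grouping: A strains carry every trait gene
        pres = truth.presence_bool()
        for s in list(groups):
            col = truth.strains.index(s)
            ids = [truth.gene_ids.index(g) for g in truth.trait_gene_ids]
            groups[s] = "A" if all(pres[i, col] for i in ids) else "B"
        traits = TraitTable(groups, trait_name="planted_trait")

    qc = filter_selfself_background(arrays.selfself, k=background_k)
    if anova_policy != "none":
        qc = qc.merge(anova_probe_filter(arrays.tensor, policy=anova_policy))
    tensor = arrays.tensor.subset_probes(qc.kept)
    rm = average_replicates(tensor)
    fits = fit_all_strains(rm)
    P = call_presence(fits, rm, cutoff=cutoff)
    hits = associate(P, traits, rule=rule)

    hit_ids = {h.gene_id for h in hits}
    planted = list(truth.trait_gene_ids)
    recovered = [g for g in planted if g in hit_ids]
    matched = truth_matching_genes(truth, traits, rule)
    false_hits = [g for g in sorted(hit_ids) if g not in set(planted)]
    return RecoveryResult(hits=hits, planted=planted, recovered=recovered,
                          false_hits=false_hits, truth_matched=matched)
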