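"""Trait-association filter: exact semantics against brute-force enumeration."""

import numpy as np
import pytest

from genomotyper import (AssociationRule, ConfigError, SimulationConfig, TraitTable,
                         associate, recover_planted_traits, simulate_experiment)
from genomotyper.association import truth_matching_genes

from conftest import make_presence


def brute_force_hits(P, traits, rule, excluded):
    """Independent oracle: enumerate every gene and count mismatches directly."""
    A = [s for s in traits.group("A") if s not in excluded]
    B = [s for s in traits.group("B") if s not in excluded]
    out = []
    for gi, g in enumerate(P.probe_ids):
        fn = sum(1 for s in A if P.P[gi, P.strains.index(s)] == 0)
        fp = sum(1 for s in B if P.P[gi, P.strains.index(s)] == 1)
        if fn <= rule.max_fn and fp <= rule.max_fp and fn + fp <= rule.max_total:
            out.append(g)
    return sorted(out)


def split_traits(strains, k):
    return TraitTable({s: ("A" if i < k else "B") for i, s in enumerate(strains)})


def test_perfect_match_is_a_hit_with_class():
    rng = np.random.default_rng(0)
    P = make_presence(rng, 10, list("abcdef"))
    P.P[0] = [1, 1, 1, 0, 0, 0]
    traits = split_traits(P.strains, 3)
    hits = {h.gene_id: h for h in associate(P, traits)}
    assert "g0000" in hits and hits["g0000"].match_class == "perfect"


def test_one_fn_and_one_fp_jointly_rejected_by_default():
    P = make_presence(np.random.default_rng(1), 1, list("abcdef"))
    P.P[0] = [0, 1, 1, 1, 0, 0]        # fn=1 (a missing) and fp=1 (d present)
    traits = split_traits(P.strains, 3)
    assert associate(P, traits) == []
    # the one-of-each reading is available behind max_total
    hits = associate(P, traits, AssociationRule(1, 1, 2))
    assert [h.gene_id for h in hits] == ["g0000"]


@pytest.mark.parametrize("rule", [
    AssociationRule(0, 0, 0), AssociationRule(1, 0, 1), AssociationRule(0, 1, 1),
    AssociationRule(1, 1, 1), AssociationRule(1, 1, 2), AssociationRule(2, 2, 4),
])
def test_hit_lists_equal_brute_force_enumeration(rule):
    rng = np.random.default_rng(42)
    P = make_presence(rng, 500, [f"s{i}" for i in range(12)], p=0.55)
    traits = split_traits(P.strains, 6)
    hits = sorted(h.gene_id for h in associate(P, traits, rule))
    assert hits == brute_force_hits(P, traits, rule, excluded=set())


def test_tightening_the_rule_is_anti_monotone():
    rng = np.random.default_rng(7)
    P = make_presence(rng, 500, [f"s{i}" for i in range(12)], p=0.55)
    traits = split_traits(P.strains, 6)
    prev = None
    for rule in (AssociationRule(2, 2, 4), AssociationRule(1, 1, 2),
                 AssociationRule(1, 1, 1), AssociationRule(1, 0, 1),
                 AssociationRule(0, 0, 0)):
        cur = {h.gene_id for h in associate(P, traits, rule)}
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_zero_tolerance_equals_set_algebra():
    rng = np.random.default_rng(8)
    P = make_presence(rng, 300, [f"s{i}" for i in range(10)], p=0.5)
    traits = split_traits(P.strains, 5)
    hits = {h.gene_id for h in associate(P, traits, AssociationRule(0, 0, 0))}
    a_idx = [P.strains.index(s) for s in traits.group("A")]
    b_idx = [P.strains.index(s) for s in traits.group("B")]
    algebra = {g for gi, g in enumerate(P.probe_ids)
               if P.P[gi, a_idx].all() and not P.P[gi, b_idx].any()}
    assert hits == algebra


def test_label_swap_searches_the_reverse_direction():
    """Swapping A and B asks for B-present/A-absent genes, not the same set."""
    rng = np.random.default_rng(9)
    P = make_presence(rng, 400, [f"s{i}" for i in range(10)], p=0.5)
    fwd = split_traits(P.strains, 5)
    rev = TraitTable({s: ("B" if v == "A" else "A") for s, v in fwd.labels.items()})
    h_fwd = {h.gene_id for h in associate(P, fwd, AssociationRule(0, 0, 0))}
    h_rev = {h.gene_id for h in associate(P, rev, AssociationRule(0, 0, 0))}
    a_idx = [P.strains.index(s) for s in fwd.group("A")]
    b_idx = [P.strains.index(s) for s in fwd.group("B")]
    reverse_algebra = {g for gi, g in enumerate(P.probe_ids)
                       if P.P[gi, b_idx].all() and not P.P[gi, a_idx].any()}
    assert h_rev == reverse_algebra
    assert not (h_fwd and h_fwd == h_rev)


def test_reference_and_outgroups_are_excluded_from_scoring():
    rng = np.random.default_rng(10)
    strains = ["ref"] + [f"s{i}" for i in range(6)] + ["og1"]
    P = make_presence(rng, 50, strains, reference="ref", outgroups=["og1"])
    P.P[0] = [1, 1, 1, 1, 0, 0, 0, 1]   # ref present, og1 present: both ignored
    labels = {s: ("A" if s in ("s0", "s1", "s2") else "B") for s in strains[1:-1]}
    labels["ref"] = "A"
    labels["og1"] = "B"
    hits = {h.gene_id for h in associate(P, TraitTable(labels),
                                         AssociationRule(0, 0, 0))}
    assert "g0000" in hits


def test_error_on_missing_strain_and_empty_group():
    rng = np.random.default_rng(11)
    P = make_presence(rng, 10, ["a", "b"])
    with pytest.raises(ConfigError, match="ghost"):
        associate(P, TraitTable({"a": "A", "ghost": "B"}))
    with pytest.raises(ConfigError, match="empty"):
        associate(P, TraitTable({"a": "A", "b": "excluded"}))


class TestPlantedRecovery:
    def test_low_noise_recovery_is_exact(self):
        cfg = SimulationConfig(n_genes=3000, present_sd=0.05, seed=17)
        truth, arrays = simulate_experiment(cfg)
        res = recover_planted_traits(truth, arrays)
        assert res.sensitivity == 1.0
        # every called hit is either planted or its random loss pattern
        # genuinely matches the split (enumerated from the truth matrix)
        matched = set(res.truth_matched)
        assert set(h.gene_id for h in res.hits) <= matched
        assert set(res.false_hits) <= matched - set(res.planted)

    def test_default_conditions_sensitivity(self, default_sim):
        _, truth, arrays = default_sim
        res = recover_planted_traits(truth, arrays)
        assert res.sensitivity >= 0.9

    def test_shuffled_labels_drop_recovery_to_chance(self, default_sim):
        cfg, truth, arrays = default_sim
        groups = cfg.trait_groups()
        strains = sorted(groups)
        rng = np.random.default_rng(99)
        shuffled = dict(zip(strains, [groups[s] for s in rng.permutation(strains)]))
        traits = TraitTable(shuffled, trait_name="shuffled")
        res = recover_planted_traits(truth, arrays, traits=traits)
        # chance level from the truth side: planted genes that happen to
        # match the shuffled split
        chance = set(truth_matching_genes(truth, traits)) & set(res.planted)
        assert set(res.recovered) <= chance
        assert res.sensitivity <= max(0.1, len(chance) / len(res.planted))
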