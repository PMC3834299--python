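"""Intensity/trait table IO, packaged phenotype fixtures, Newick output."""

import numpy as np
import pytest
import dendropy
from hypothesis import given, settings, strategies as st

from genomotyper import (ConfigError, FormatError, LogRatioTensor,
                         load_trait_fixture, read_intensity_table,
                         write_intensity_table, write_newick)
from genomotyper.arrayio import load_lysis_matrix, normalize_strain_name, read_trait_table
from genomotyper.trees import Node, bipartitions, to_newick

LONG_HEADER = "probe_id\tstrain\treplicate\tlog2_ratio\n"


def write(tmp_path, text, name="t.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_long_parse_shape_and_order(tmp_path):
    p = write(tmp_path, LONG_HEADER +
              "p3\tsB\t1\t0.5\np1\tsB\t1\t-1.0\np2\tsA\t1\t0.25\n"
              "p3\tsA\t1\t0\np1\tsA\t1\t2\np2\tsB\t1\t1\n")
    t = read_intensity_table(p)
    assert t.probe_ids == ["p3", "p1", "p2"]          # first-occurrence order
    assert t.strains == ["sB", "sA"]
    assert t.values.shape == (3, 2, 1)
    assert t.values[0, 1, 0] == 0.0 and t.values[1, 0, 0] == -1.0


def test_duplicate_key_reports_line(tmp_path):
    p = write(tmp_path, LONG_HEADER + "p1\ts1\t1\t0.5\np1\ts1\t1\t0.7\n")
    with pytest.raises(FormatError, match="line 3"):
        read_intensity_table(p)


def test_malformed_numeric_reports_line(tmp_path):
    p = write(tmp_path, LONG_HEADER + "p1\ts1\t1\t0.5\np2\ts1\t1\tbogus\n")
    with pytest.raises(FormatError, match="line.*3"):
        read_intensity_table(p)


def test_missing_column_is_a_format_error(tmp_path):
    p = write(tmp_path, "probe_id\tstrain\tlog2_ratio\np1\ts1\t0.5\n")
    with pytest.raises(FormatError, match="replicate"):
        read_intensity_table(p)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_round_trip_preserves_values_to_12_digits(tmp_path, seed):
    rng = np.random.default_rng(seed)
    G, S, R = rng.integers(2, 12, size=3)
    t = LogRatioTensor([f"p{i}" for i in range(G)], [f"s{i}" for i in range(S)],
                       rng.normal(0, 2, size=(G, S, R)))
    p = tmp_path / "rt.tsv"
    write_intensity_table(t, p)
    u = read_intensity_table(p)
    assert u.probe_ids == t.probe_ids and u.strains == t.strains
    np.testing.assert_allclose(u.values, t.values, rtol=1e-11, atol=0)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(1, 8), st.integers(1, 5), st.integers(1, 4),
       st.floats(-50, 50, allow_nan=False).map(lambda c: c / 7))
def test_round_trip_any_shape_and_offset(tmp_path_factory, G, S, R, offset):
    """Property: write->read is the identity on tensors of any shape, with
    values anywhere in the plausible log-ratio range."""
    rng = np.random.default_rng(G * 100 + S * 10 + R)
    t = LogRatioTensor([f"p{i}" for i in range(G)], [f"s{i}" for i in range(S)],
                       rng.normal(offset, 1.5, size=(G, S, R)))
    p = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_intensity_table(t, p)
    u = read_intensity_table(p)
    assert (u.probe_ids, u.strains) == (t.probe_ids, t.strains)
    np.testing.assert_allclose(u.values, t.values, rtol=1e-11, atol=1e-13)


def test_writer_is_deterministic(tmp_path):
    rng = np.random.default_rng(3)
    t = LogRatioTensor(["a", "b"], ["x", "y"], rng.normal(size=(2, 2, 3)))
    p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
    write_intensity_table(t, p1)
    write_intensity_table(t, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_wide_format_matches_long(tmp_path):
    long = write(tmp_path, LONG_HEADER +
                 "p1\ts1\t1\t0.5\np1\ts1\t2\t0.7\np1\ts2\t1\t-1\np1\ts2\t2\t-2\n",
                 "long.tsv")
    wide = write(tmp_path, "probe_id\ts1|1\ts1|2\ts2|1\ts2|2\np1\t0.5\t0.7\t-1\t-2\n",
                 "wide.tsv")
    a, b = read_intensity_table(long), read_intensity_table(wide, fmt="wide")
    np.testing.assert_allclose(a.values, b.values)


class TestTraitFixtures:
    def test_coccolith_fixture_matches_published_strain_table(self):
        traits = load_trait_fixture("coccoliths")
        assert len(traits.labels) == 16
        assert traits.labels["CCMP1516"] == "A"   # calcifying
        assert traits.labels["Van 556"] == "B"    # non-calcifying
        assert sorted(traits.group("A")) == sorted(
            ["92D", "92E", "92F", "12-1", "CCMP1516", "CH 24/90", "CH 25/90",
             "NZEH", "EH2"])

    def test_virus_fixture_default_rule(self):
        traits = load_trait_fixture("virus_susceptibility")
        assert traits.labels["92F"] == "A"        # lysed by all nine viruses
        assert traits.labels["NZEH"] == "B"       # lysed by none
        assert traits.labels["CH 24/90"] == "A"   # one lysis event suffices by default

    def test_virus_fixture_min_lysed_rule(self):
        # CH 24/90 is lysed by exactly one virus strain (EhV-208)
        m = load_lysis_matrix()
        assert (m.loc["CH 24/90"] == "+").sum() == 1
        assert m.loc["CH 24/90", "EhV-208"] == "+"
        traits = load_trait_fixture("virus_susceptibility", min_lysed=2)
        assert traits.labels["CH 24/90"] == "B"
        assert traits.labels["12-1"] == "A"       # seven lysis events

    def test_lysis_matrix_shape(self):
        m = load_lysis_matrix()
        assert m.shape == (16, 9)

    def test_unknown_fixture_name(self):
        with pytest.raises(ConfigError):
            load_trait_fixture("nope")

    def test_strain_alias_normalization(self):
        assert normalize_strain_name("12-1 ( = CCMP371) (Sargasso Sea)") == "12-1"
        assert normalize_strain_name("CCMP371") == "12-1"
        assert normalize_strain_name("92F") == "92F"


def test_generic_trait_table_roundtrip(tmp_path):
    p = write(tmp_path, "strain\tgroup\nx\tA\ny\tB\nz\texcluded\n", "tr.tsv")
    t = read_trait_table(p)
    assert t.group("A") == ["x"] and t.group("B") == ["y"]
    with pytest.raises(ConfigError):
        read_trait_table(write(tmp_path, "strain\tgroup\nx\tQ\n", "bad.tsv"))


class TestNewick:
    def test_three_leaf_star(self):
        root = Node(children=[Node(name="a", length=1), Node(name="b", length=1),
                              Node(name="c", length=1)])
        assert to_newick(root) == "(a:1,b:1,c:1);"

    def test_support_becomes_internal_label(self):
        inner = Node(support=87, children=[Node(name="a", length=1),
                                           Node(name="b", length=1)], length=0.5)
        root = Node(children=[inner, Node(name="c", length=1), Node(name="d", length=1)])
        assert to_newick(root) == "((a:1,b:1)87:0.5,c:1,d:1);"

    def test_external_parser_agrees_on_bipartitions(self, tmp_path):
        rng = np.random.default_rng(5)
        leaves = [Node(name=f"t{i}", length=float(rng.uniform(0.1, 2))) for i in range(8)]
        while len(leaves) > 3:
            a, b = leaves.pop(0), leaves.pop(0)
            leaves.append(Node(children=[a, b], length=float(rng.uniform(0.1, 2))))
        root = Node(children=leaves)
        p = tmp_path / "t.nwk"
        write_newick(root, p)
        tree = dendropy.Tree.get(path=str(p), schema="newick")
        tree.encode_bipartitions()
        names = root.leaf_names()
        anchor = min(names)
        external = set()
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is None or edge.head_node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
            if anchor in side:
                side = frozenset(names) - side
            if 1 < len(side) < len(names) - 1:
                external.add(side)
        assert external == bipartitions(root)
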