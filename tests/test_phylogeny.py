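"""Binary distances, neighbour joining against independent oracles, bootstrap."""

import dendropy
import numpy as np
import pytest

from genomotyper import (ConfigError, DistanceMatrix, binary_distance,
                         bootstrap_consensus, neighbor_joining)
from genomotyper.trees import Node, bipartitions, leaf_distances, to_newick

from conftest import make_presence


def canonical(side, leaves):
    """Bipartition side canonicalized as in genomotyper.trees (the side
    without the alphabetically first leaf)."""
    side = frozenset(side)
    return frozenset(leaves) - side if min(leaves) in side else side


def random_additive(rng, n):
    """Random binary tree with uniform(0.5, 5) lengths and its leaf-distance
    matrix — the generating tree is the oracle for NJ recovery."""
    taxa = [f"t{i}" for i in range(n)]
    nodes = [Node(name=t, length=float(rng.uniform(0.5, 5))) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        nodes.append(Node(children=[a, b], length=float(rng.uniform(0.5, 5))))
    root = Node(children=nodes)
    dist = leaf_distances(root)
    D = np.zeros((n, n))
    for (x, y), d in dist.items():
        ix, iy = taxa.index(x), taxa.index(y)
        D[ix, iy] = D[iy, ix] = d
    return root, DistanceMatrix(taxa, D)


def rf_distance(a: Node, b: Node) -> int:
    """Robinson–Foulds via an independent library."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=to_newick(a), schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=to_newick(b), schema="newick", taxon_namespace=tns)
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestBinaryDistance:
    def test_identical_and_complementary_columns(self):
        P = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0], [0, 0, 1]])
        D = binary_distance(P, strains=["a", "b", "c"]).values
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0

    def test_matches_brute_force_mismatch_count(self):
        rng = np.random.default_rng(14)
        M = (rng.random((200, 6)) < 0.5).astype(int)
        D = binary_distance(M).values
        for s in range(6):
            for t in range(6):
                assert D[s, t] == pytest.approx(
                    sum(abs(M[g, s] - M[g, t]) for g in range(200)) / 200)

    def test_jaccard_option(self):
        M = np.array([[1, 1, 1], [1, 0, 1], [0, 1, 1], [0, 0, 1]])
        D = binary_distance(M, metric="jaccard").values
        assert D[0, 1] == pytest.approx(2 / 3)
        assert D[0, 2] == pytest.approx(2 / 4)

    def test_errors(self):
        with pytest.raises(ConfigError):
            binary_distance(np.ones((0, 4)))
        with pytest.raises(ConfigError):
            binary_distance(np.ones((5, 2)))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = neighbor_joining(D)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0),
                           "c": pytest.approx(3.0)}

    def test_four_taxon_known_tree_recovered_exactly(self):
        # ((a:1,b:2):5,c:3,d:4) — additive by construction
        true = Node(children=[
            Node(children=[Node(name="a", length=1), Node(name="b", length=2)],
                 length=5),
            Node(name="c", length=3), Node(name="d", length=4)])
        dist = leaf_distances(true)
        taxa = ["a", "b", "c", "d"]
        D = np.zeros((4, 4))
        for (x, y), d in dist.items():
            D[taxa.index(x), taxa.index(y)] = D[taxa.index(y), taxa.index(x)] = d
        tree = neighbor_joining(DistanceMatrix(taxa, D))
        assert rf_distance(tree, true) == 0
        got = leaf_distances(tree)
        for k, v in dist.items():
            assert got[k] == pytest.approx(v, abs=1e-9)

    @pytest.mark.parametrize("seed", range(15))
    def test_additive_eight_taxon_matrices_recovered(self, seed):
        rng = np.random.default_rng(seed)
        true, dm = random_additive(rng, 8)
        tree = neighbor_joining(dm)
        assert rf_distance(tree, true) == 0
        got, want = leaf_distances(tree), leaf_distances(true)
        assert max(abs(got[k] - want[k]) for k in want) < 1e-9

    def test_input_order_invariance(self):
        rng = np.random.default_rng(77)
        _, dm = random_additive(rng, 7)
        perm = rng.permutation(7)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
        assert bipartitions(t1) == bipartitions(t2)
        assert leaf_distances(t1) == pytest.approx(leaf_distances(t2))

    def test_validation_errors(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ConfigError):
            neighbor_joining(DistanceMatrix(["a", "b"], bad))
        neg = np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ConfigError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], neg))


class TestBootstrap:
    def two_clade(self):
        P = np.zeros((200, 10), dtype=np.int8)
        P[:100, :5] = 1
        P[100:, 5:] = 1
        ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        return P, ids

    def test_perfectly_separated_clades_get_full_support(self):
        P, ids = self.two_clade()
        st = bootstrap_consensus(P, B=200, seed=3, strains=ids)
        clade = frozenset(f"b{i}" for i in range(5))
        assert st.supports[clade] == 100.0

    def test_seeded_determinism(self):
        P, ids = self.two_clade()
        a = bootstrap_consensus(P, B=50, seed=9, strains=ids)
        b = bootstrap_consensus(P, B=50, seed=9, strains=ids)
        assert a.supports == b.supports
        assert to_newick(a.tree) == to_newick(b.tree)

    def test_supports_invariant_to_strain_column_order(self):
        rng = np.random.default_rng(21)
        P = (rng.random((300, 6)) < 0.6).astype(np.int8)
        ids = list("abcdef")
        a = bootstrap_consensus(P, B=40, seed=5, strains=ids)
        perm = rng.permutation(6)
        b = bootstrap_consensus(P[:, perm], B=40, seed=5,
                                strains=[ids[i] for i in perm])
        assert a.supports == b.supports

    def test_consensus_contains_only_majority_bipartitions(self):
        rng = np.random.default_rng(30)
        P = (rng.random((120, 7)) < 0.5).astype(np.int8)
        st = bootstrap_consensus(P, B=60, seed=2, strains=list("abcdefg"))
        for bip in bipartitions(st.tree):
            assert st.supports[bip] > 50.0

    def test_full_tree_carries_painted_supports(self):
        P, ids = self.two_clade()
        st = bootstrap_consensus(P, B=30, seed=1, strains=ids)
        painted = [n.support for n in st.full_tree.walk()
                   if not n.is_leaf and n.support is not None]
        assert painted and all(0 <= s <= 100 for s in painted)

    def test_replicate_count_validation(self):
        P, ids = self.two_clade()
        with pytest.raises(ConfigError):
            bootstrap_consensus(P, B=0, strains=ids)


def test_outgroup_scenario_support():
    """Outgroup taxa with ~30% gene-content divergence split off from the
    conspecific strains with near-total support (the dendrogram's anchor)."""
    from genomotyper import SimulationConfig, partition, simulate_experiment
    from genomotyper.calling import call_presence, fit_all_strains
    from genomotyper.preprocess import average_replicates, filter_selfself_background

    cfg = SimulationConfig(seed=7, n_strains=8, n_outgroups=2, n_genes=3000,
                           n_reference_specific=20)
    _, arrays = simulate_experiment(cfg)
    qc = filter_selfself_background(arrays.selfself)
    rm = average_replicates(arrays.tensor.subset_probes(qc.kept))
    P = call_presence(fit_all_strains(rm), rm)
    assert partition(P).dissimilarity_pct["og1"] >= 25.0
    st = bootstrap_consensus(P, B=100, seed=7)
    assert st.supports.get(canonical({"og1", "og2"}, P.strains), 0.0) >= 99.0
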