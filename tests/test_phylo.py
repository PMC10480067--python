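"""K2P distances, neighbour-joining, patristic distances, standardization."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, strategies as st
from skbio import DistanceMatrix

from fpdiv import (
    AlignedSequences,
    SaturationError,
    SitePairCounts,
    bootstrap_support,
    count_site_pairs,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    patristic_matrix,
    simulate_sequences,
    simulate_tree,
    standardize_unit,
)
from fpdiv.phylo import _internal_splits


class TestSitePairCounts:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (4, 0, 0)),
            ("ACGT", "GCGT", (4, 1, 0)),  # A<->G is a transition
            ("AC-T", "ACGT", (3, 0, 0)),  # gap site dropped pairwise
            ("ACGT", "ACGA", (4, 0, 1)),  # T<->A is a transversion
            ("NCGT", "ACGT", (3, 0, 0)),  # N treated as missing
        ],
    )
    def test_counts(self, a, b, expected):
        assert count_site_pairs(a, b) == expected

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError, match="no overlap"):
            count_site_pairs("--AC", "GT--")


class TestK2PDistance:
    def test_identical_is_zero(self):
        assert k2p_distance(SitePairCounts(100, 0, 0)) == 0.0

    def test_closed_form_case(self):
        # P=0.10, Q=0.05: d = -1/2 ln(0.75 * sqrt(0.90))
        d = k2p_distance(SitePairCounts(100, 10, 5))
        assert d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.90)), abs=1e-12)
        assert d == pytest.approx(0.17018, abs=5e-6)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            k2p_distance(SitePairCounts(10, 5, 0))  # 1 - 2P - Q = 0

    def test_taylor_limit_matches_p_distance(self):
        # d -> P + Q as P,Q -> 0 (first-order agreement within 1%)
        for n, ts, tv in [(10000, 40, 30), (100000, 500, 400), (100000, 9, 1)]:
            d = k2p_distance(SitePairCounts(n, ts, tv))
            p_dist = (ts + tv) / n
            assert d == pytest.approx(p_dist, rel=0.01)


class TestK2PMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = AlignedSequences({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        assert np.all(k2p_matrix(aln).data == 0.0)

    def test_two_sequences(self):
        aln = AlignedSequences({"a": "AAAAAAAAAA", "b": "AAAAAAAAGG"})
        dm = k2p_matrix(aln)
        assert dm.shape == (2, 2)
        assert dm.data[0, 1] == pytest.approx(
            k2p_distance(SitePairCounts(10, 2, 0)), abs=1e-15
        )

    def test_failing_pair_is_named(self):
        aln = AlignedSequences({"a": "ACACACACAC", "b": "GTGTGTGTGT", "c": "ACACACACAC"})
        with pytest.raises(ValueError, match="'a'.*'b'"):
            k2p_matrix(aln)

    def test_recovers_simulated_divergence(self):
        # sequences simulated under K2P on a two-leaf path of known length:
        # estimate within 3 Monte-Carlo standard errors
        tree = dendropy.Tree.get(data="(A:0.05,B:0.05);", schema="newick")
        aln = simulate_sequences(tree, length=100_000, kappa=2.0, seed=5)
        d = k2p_matrix(aln).data[0, 1]
        se = math.sqrt(0.1 / 100_000)  # coarse binomial-scale SE
        assert abs(d - 0.1) < 3 * max(se, 1.5e-3)


def _random_additive_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    tree = simulate_tree(n_taxa, seed)
    rng = np.random.default_rng(seed)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * rng.uniform(0.5, 2.0) + 0.005)
    return tree


class TestNeighbourJoining:
    def test_three_taxon_exact_branches(self):
        dm = DistanceMatrix(
            [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], ids=["A", "B", "C"]
        )
        tree = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.05, abs=1e-12)
        assert lengths["B"] == pytest.approx(0.15, abs=1e-12)
        assert lengths["C"] == pytest.approx(0.25, abs=1e-12)

    def test_four_taxon_topology_recovery(self):
        # ((A,B),(C,D)) with internal branch 0.1
        tree_in = dendropy.Tree.get(
            data="((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.0);", schema="newick"
        )
        dm = patristic_matrix(tree_in, labels=["A", "B", "C", "D"])
        tree_out = nj_tree(dm)
        splits = set(_internal_splits(tree_out).values())
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits

    def test_zero_matrix_gives_zero_branches(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("ABCD"))
        tree = nj_tree(dm)
        for edge in tree.preorder_edge_iter():
            assert not edge.length  # None at root, 0.0 elsewhere

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))

    @pytest.mark.parametrize("seed", range(25))
    def test_additive_matrix_reproduced(self, seed):
        """On additive input, NJ's patristic distances equal the input."""
        n = 4 + seed % 9
        tree = _random_additive_tree(n, seed + 100)
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        dm = patristic_matrix(tree, labels=labels)
        out = patristic_matrix(nj_tree(dm), labels=labels)
        np.testing.assert_allclose(out.data, dm.data, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_independent_nj(self, seed):
        """Same unrooted topology as scikit-bio's NJ on near-additive input."""
        from skbio.tree import nj as skbio_nj

        tree = _random_additive_tree(5 + seed, seed)
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        data = patristic_matrix(tree, labels=labels).data
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, 1e-6, size=data.shape)
        noise = noise + noise.T
        np.fill_diagonal(noise, 0.0)
        dm = DistanceMatrix(data + noise, ids=labels)
        mine = set(_internal_splits(nj_tree(dm)).values())
        all_labels = frozenset(labels)
        ref = min(all_labels)
        theirs = set()
        for side in (frozenset(s) for s in skbio_nj(dm).subsets()):
            side = side if ref not in side else all_labels - side
            if 2 <= len(side) <= len(all_labels) - 2:
                theirs.add(side)
        assert mine == theirs


class TestPatristic:
    def test_single_cherry_additivity(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.2);", schema="newick")
        dm = patristic_matrix(tree, labels=["A", "B"])
        assert dm.data[0, 1] == pytest.approx(0.3, abs=1e-15)

    def test_inverts_three_point_solution(self):
        dm_in = DistanceMatrix(
            [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], ids=["A", "B", "C"]
        )
        dm_out = patristic_matrix(nj_tree(dm_in), labels=["A", "B", "C"])
        np.testing.assert_allclose(dm_out.data, dm_in.data, atol=1e-12)

    def test_zero_branches_zero_matrix(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,C:0);", schema="newick")
        assert np.all(patristic_matrix(tree, labels=["A", "B", "C"]).data == 0)


class TestStandardizeUnit:
    def test_scales_by_max(self):
        dm = DistanceMatrix(
            [[0, 0.2, 0.4], [0.2, 0, 0.8], [0.4, 0.8, 0]], ids=list("abc")
        )
        out = standardize_unit(dm)
        np.testing.assert_allclose(
            out.data, [[0, 0.25, 0.5], [0.25, 0, 1.0], [0.5, 1.0, 0]]
        )

    def test_idempotent(self):
        dm = DistanceMatrix([[0, 0.3, 1.0], [0.3, 0, 0.6], [1.0, 0.6, 0]], ids=list("abc"))
        once = standardize_unit(dm)
        twice = standardize_unit(once)
        np.testing.assert_array_equal(once.data, twice.data)

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariant(self, scale):
        base = np.array([[0, 0.2, 0.7], [0.2, 0, 0.5], [0.7, 0.5, 0]])
        a = standardize_unit(DistanceMatrix(base, ids=list("abc")))
        b = standardize_unit(DistanceMatrix(base * scale, ids=list("abc")))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            standardize_unit(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))


class TestBootstrap:
    def test_identical_sequences_complete(self):
        aln = AlignedSequences({k: "ACGTACGTACGT" for k in "abcd"})
        tree = bootstrap_support(aln, n_reps=5, seed=0)
        assert len(tree.leaf_nodes()) == 4

    def test_single_replicate_support_is_binary(self):
        tree = simulate_tree(6, 3)
        aln = simulate_sequences(tree, length=300, seed=3)
        boot = bootstrap_support(aln, n_reps=1, seed=1)
        supports = [
            float(nd.label)
            for nd in boot.preorder_node_iter()
            if nd.label is not None and not nd.is_leaf()
        ]
        assert supports and all(s in (0.0, 1.0) for s in supports)

    def test_deep_split_gets_high_support(self):
        # two clades of three separated by a long internal branch
        source = dendropy.Tree.get(
            data="((a1:0.01,a2:0.01,a3:0.01):0.15,"
            "(b1:0.01,b2:0.01,b3:0.01):0.15);",
            schema="newick",
        )
        aln = simulate_sequences(source, length=600, seed=2)
        tree = bootstrap_support(aln, n_reps=100, seed=2)
        splits = _internal_splits(tree)
        support = {
            frozenset(side): float(nd.label)
            for nd in tree.preorder_node_iter()
            if id(nd) in splits
            for side in [splits[id(nd)]]
        }
        deep = frozenset({"b1", "b2", "b3"})
        assert support[deep] > 0.95
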