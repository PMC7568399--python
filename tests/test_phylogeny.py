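"""Distances, neighbor joining, and rooting.

The NJ checks use three independent oracles: the 3-taxon closed form, a
brute-force enumeration of 5-taxon topologies with least-squares edge
fitting on additive matrices, and scikit-bio's NJ implementation.
"""

import itertools

import dendropy
import numpy as np
import pytest

from phyloconsensus.errors import TreeError, UndefinedDistanceError, ValidationError
from phyloconsensus.family_io import AlignedFamily
from phyloconsensus.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    distance_matrix,
    neighbor_joining,
    pairwise_distance,
    root_with_outgroup,
    tree_splits,
)


class TestPairwiseDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AAAA", "AAAA", 0.0),
            ("AAAT", "AAAA", 0.25),       # 1 differing pair / min length 4
            ("AA-A", "AATA", 0.0),        # gap column ignored
            ("AC-A", "AATA", 1 / 3),      # 1 mismatch / min ungapped length 3
        ],
    )
    def test_hand_counted_examples(self, a, b, expected):
        assert pairwise_distance(a, b) == pytest.approx(expected)

    def test_symmetric(self):
        assert pairwise_distance("ACD-", "AW-E") == pairwise_distance("AW-E", "ACD-")

    def test_all_gap_sequence_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            pairwise_distance("----", "ACDE")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_distance("AC", "ACD")


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        fam = AlignedFamily((("a", "ACDE"), ("b", "ACDE")), "a")
        dm = distance_matrix(fam)
        assert np.all(dm.d == 0)

    def test_hand_counted_three_sequences(self):
        fam = AlignedFamily(
            (("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")), "a"
        )
        dm = distance_matrix(fam)
        assert dm["a", "b"] == pytest.approx(0.25)
        assert dm["a", "c"] == pytest.approx(0.5)
        assert dm["b", "c"] == pytest.approx(0.25)

    def test_permutation_consistency(self):
        fam1 = AlignedFamily(
            (("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")), "a"
        )
        fam2 = AlignedFamily(
            (("c", "AATT"), ("a", "AAAA"), ("b", "AAAT")), "a"
        )
        dm1, dm2 = distance_matrix(fam1), distance_matrix(fam2)
        for x, y in itertools.combinations("abc", 2):
            assert dm1[x, y] == dm2[x, y]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -0.1], [-0.1, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d_ab, d_ac, d_bc = 0.2, 0.3, 0.4
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
        )
        tree = neighbor_joining(dm)
        limbs = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        assert limbs["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2, abs=1e-12)
        assert limbs["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2, abs=1e-12)
        assert limbs["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2, abs=1e-12)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 0.4], [0.4, 0]]))
        tree = neighbor_joining(dm)
        assert tree.path_length("A", "B") == pytest.approx(0.4)

    @pytest.mark.parametrize("newick", [
        "((A:0.11,B:0.07):0.05,(C:0.04,D:0.09):0.03);",
        "((A:0.11,B:0.07):0.05,(C:0.04,D:0.09):0.03,E:0.13);",
        "(((A:0.06,B:0.09):0.04,(C:0.05,D:0.12):0.07):0.03,E:0.1,F:0.08);",
    ])
    def test_additive_matrix_recovers_generating_tree(self, newick):
        truth = PhyloTree.from_newick(newick)
        ids = sorted(truth.leaf_labels)
        D = truth.path_length_matrix(ids)
        tree = neighbor_joining(DistanceMatrix(tuple(ids), D))
        assert tree_splits(tree) == tree_splits(truth)
        # additive => NJ reproduces the metric exactly
        assert np.allclose(tree.path_length_matrix(ids), D, atol=1e-9)

    def test_five_taxon_brute_force_topology_oracle(self):
        """On an additive matrix, exhaustive enumeration of all 15 unrooted
        5-taxon topologies finds exactly one with a perfect least-squares
        fit, and NJ returns it."""
        truth = PhyloTree.from_newick(
            "((A:0.11,B:0.07):0.05,(C:0.04,D:0.09):0.03,E:0.13);"
        )
        ids = sorted(truth.leaf_labels)
        D = truth.path_length_matrix(ids)
        pairs = list(itertools.combinations(range(5), 2))

        def residual(splits):
            # columns: 5 terminal edges + one per internal split
            A = np.zeros((len(pairs), 5 + len(splits)))
            for row, (i, j) in enumerate(pairs):
                A[row, i] = A[row, j] = 1.0
                for s_idx, side in enumerate(splits):
                    if (i in side) != (j in side):
                        A[row, 5 + s_idx] = 1.0
            y = np.array([D[i, j] for i, j in pairs])
            coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            fit = A @ coef
            return float(((fit - y) ** 2).sum())

        perfect = []
        two_subsets = [frozenset(c) for c in itertools.combinations(range(5), 2)]
        for s1, s2 in itertools.combinations(two_subsets, 2):
            if s1 & s2:
                continue  # incompatible splits
            if residual([s1, s2]) < 1e-18:
                perfect.append({s1, s2})
        assert len(perfect) == 1
        index_splits = {
            frozenset(sorted(ids).index(l) for l in side)
            for side in tree_splits(neighbor_joining(DistanceMatrix(tuple(ids), D)))
        }
        # canonicalize each enumerated split to the side without taxon 0
        canon = {
            s if 0 not in s else frozenset(range(5)) - s for s in perfect[0]
        }
        assert index_splits == canon

    def test_matches_scikit_bio_on_perturbed_additive_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        truth = PhyloTree.from_newick(
            "(((A:0.06,B:0.09):0.04,(C:0.05,D:0.12):0.07):0.03,E:0.1,F:0.08);"
        )
        ids = sorted(truth.leaf_labels)
        D = truth.path_length_matrix(ids)
        noise = rng.uniform(-0.004, 0.004, size=D.shape)
        D = np.abs(D + (noise + noise.T))
        D = (D + D.T) / 2.0  # enforce bit-level symmetry
        np.fill_diagonal(D, 0.0)
        mine = neighbor_joining(DistanceMatrix(tuple(ids), D))
        ref = skbio_nj(SkbioDM(D, ids))
        ref_tree = PhyloTree.from_newick(str(ref))
        assert tree_splits(mine) == tree_splits(ref_tree)

    def test_equal_distance_tie_is_deterministic(self):
        d = 0.3
        n = 4
        D = np.full((n, n), d)
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(tuple("ABCD"), D)
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm)
        assert t1.as_newick() == t2.as_newick()
        total = sum(
            e.length or 0.0 for e in t1.tree.preorder_edge_iter()
        )
        assert total == pytest.approx(2 * d)  # closed form for the 4-taxon tie

    def test_negative_limbs_clamped_and_logged(self):
        # strongly non-additive matrix forces a negative limb estimate
        D = np.array(
            [
                [0.0, 0.1, 0.5, 0.5],
                [0.1, 0.0, 0.5, 0.5],
                [0.5, 0.5, 0.0, 0.02],
                [0.5, 0.5, 0.02, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(tuple("ABCD"), D))
        for e in tree.tree.preorder_edge_iter():
            assert e.length is None or e.length >= 0


class TestRooting:
    def _three_taxon(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        return neighbor_joining(dm)

    def test_root_children_are_outgroup_and_rest(self):
        rooted = root_with_outgroup(self._three_taxon(), "C")
        assert rooted.rooted
        children = rooted.tree.seed_node.child_nodes()
        assert len(children) == 2
        labels = {c.taxon.label if c.taxon else None for c in children}
        assert "C" in labels
        out_edge = next(
            c.edge for c in children if c.taxon and c.taxon.label == "C"
        )
        assert out_edge.length == pytest.approx(0.25 / 2)  # half the C limb

    def test_path_lengths_preserved_by_rooting(self):
        unrooted = self._three_taxon()
        rooted = root_with_outgroup(unrooted, "C")
        for a, b in itertools.combinations("ABC", 2):
            assert rooted.path_length(a, b) == pytest.approx(
                unrooted.path_length(a, b), abs=1e-12
            )

    def test_split_fraction_places_root(self):
        rooted = root_with_outgroup(self._three_taxon(), "C", split_fraction=0.2)
        out_leaf = rooted.leaf("C")
        assert out_leaf.edge.length == pytest.approx(0.25 * 0.2)
        # total edge length conserved
        sib = [c for c in rooted.tree.seed_node.child_nodes() if c is not out_leaf]
        assert out_leaf.edge.length + sib[0].edge.length == pytest.approx(0.25)

    def test_unknown_outgroup_raises(self):
        with pytest.raises(TreeError):
            root_with_outgroup(self._three_taxon(), "nope")

    def test_newick_roundtrip_identity(self):
        rooted = root_with_outgroup(self._three_taxon(), "C")
        again = PhyloTree.from_newick(rooted.as_newick(), rooted=True)
        assert tree_splits(again) == tree_splits(rooted)
        for a, b in itertools.combinations("ABC", 2):
            assert again.path_length(a, b) == pytest.approx(
                rooted.path_length(a, b), abs=1e-9
            )

    def test_rooting_leaves_input_unmodified(self):
        unrooted = self._three_taxon()
        before = unrooted.as_newick()
        root_with_outgroup(unrooted, "C")
        assert unrooted.as_newick() == before
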