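import itertools

import numpy as np
import pytest

from leptokit import treeops
from leptokit.treeops import (TreeError, build_constraint_set,
                              count_binary_resolutions, is_compatible,
                              read_newick, remove_fastest_taxa, splits,
                              strict_consensus, upgma, write_newick)

from conftest import dendropy_splits, enumerate_binary_trees


class TestNewick:
    def test_binary_four_leaf(self):
        t = read_newick("((A,B),(C,D));")
        assert sorted(treeops.leaf_labels(t)) == ["A", "B", "C", "D"]

    def test_star_tree_polytomy(self):
        t = read_newick("(A,B,C,D);")
        assert len(t.seed_node.child_nodes()) == 4

    def test_malformed_rejected(self):
        with pytest.raises(TreeError):
            read_newick("((A,B);")

    def test_round_trip_preserves_lengths(self):
        nwk = "((A:0.1234567891,B:0.2):0.05,C:1.0);"
        t = read_newick(nwk)
        back = read_newick(write_newick(t))
        assert splits(t) == splits(back)
        la = {lf.taxon.label: lf.edge.length for lf in back.leaf_node_iter()}
        assert la["A"] == pytest.approx(0.1234567891, rel=1e-9)


class TestSplits:
    def test_matches_dendropy_encoding(self):
        for nwk in ["((A,B),(C,D),E);", "(((A,B),C),(D,(E,F)));",
                    "(A,B,C,(D,E));"]:
            t = read_newick(nwk)
            assert splits(t) == dendropy_splits(t)

    def test_invariant_to_rotation(self):
        assert (splits(read_newick("((A,B),(C,D));"))
                == splits(read_newick("((D,C),(B,A));")))


class TestStrictConsensus:
    def test_identity(self):
        t = read_newick("((A,B),(C,D),E);")
        res = strict_consensus(t, read_newick("((B,A),(D,C),E);"))
        assert res.collapsed_count == 0
        assert splits(res.tree) == splits(t)

    def test_disjoint_four_taxon(self):
        res = strict_consensus(read_newick("((A,B),(C,D));"),
                               read_newick("((A,C),(B,D));"))
        assert res.collapsed_count == 1
        assert res.shared_splits == set()
        assert len(res.tree.seed_node.child_nodes()) >= 4  # star

    def test_single_nni_collapses_one(self):
        res = strict_consensus(read_newick("(((A,B),C),(D,E));"),
                               read_newick("(((A,C),B),(D,E));"))
        assert res.collapsed_count == 1
        degrees = [len(n.child_nodes()) for n in
                   res.tree.preorder_internal_node_iter()]
        assert max(degrees) >= 3  # one unresolved vertex

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(TreeError, match="differ"):
            strict_consensus(read_newick("((A,B),(C,D));"),
                             read_newick("((A,B),(C,E));"))

    def test_commutative(self):
        a = read_newick("(((A,B),C),(D,(E,F)));")
        b = read_newick("(((A,C),B),(D,(E,F)));")
        r1, r2 = strict_consensus(a, b), strict_consensus(b, a)
        assert r1.shared_splits == r2.shared_splits
        assert r1.collapsed_count == r2.collapsed_count

    @pytest.mark.parametrize("n", [5, 6])
    def test_collapsed_count_bounds_exhaustive(self, n):
        labels = [chr(65 + i) for i in range(n)]
        trees = [read_newick(nwk) for nwk in enumerate_binary_trees(labels)]
        rng = np.random.default_rng(0)
        idx = rng.choice(len(trees), size=(30, 2))
        for i, j in idx:
            res = strict_consensus(trees[i], trees[j])
            shared = dendropy_splits(trees[i]) & dendropy_splits(trees[j])
            assert res.collapsed_count == (n - 3) - len(shared)
            assert 0 <= res.collapsed_count <= n - 3


class TestResolutionCounting:
    def test_binary_tree_is_one(self):
        assert count_binary_resolutions(read_newick("((A,B),(C,D));")) == 1

    @pytest.mark.parametrize("nwk,expected", [
        ("(A,B,C,D);", 3), ("(A,B,C,D,E);", 15), ("((A,B,C),(D,E,F));", 9)])
    def test_double_factorial_products(self, nwk, expected):
        assert count_binary_resolutions(read_newick(nwk)) == expected

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_star_matches_enumeration(self, n):
        labels = [chr(65 + i) for i in range(n)]
        star = read_newick("(" + ",".join(labels) + ");")
        assert (count_binary_resolutions(star)
                == len(set(enumerate_binary_trees(labels))))

    def test_consensus_of_identical_binary_resolves_to_one(self):
        t = read_newick("(((A,B),C),(D,E));")
        assert count_binary_resolutions(strict_consensus(t, t).tree) == 1


class TestConstraints:
    GROUPS = {"leptophytes": ["L1", "L2"], "haptophytes": ["H1", "H2"],
              "cryptophytes": ["C1", "C2"], "other_red_complex": ["O1", "O2"],
              "red_algae": ["R1", "R2", "R3"]}

    def test_exactly_six_topologies(self):
        assert len(build_constraint_set(self.GROUPS)) == 6

    def test_h_sister_contains_lh_split(self):
        trees = dict(build_constraint_set(self.GROUPS))
        s = splits(trees["H-sister+CPfree"])
        assert frozenset({"L1", "L2", "H1", "H2"}) in {
            fs if "C1" not in fs else fs for fs in s} or any(
            set(fs) == {"L1", "L2", "H1", "H2"} for fs in s)

    def test_each_tree_satisfies_its_own_constraint(self):
        for _, tree in build_constraint_set(self.GROUPS):
            assert is_compatible(tree, tree)

    def test_placements_mutually_incompatible(self):
        trees = dict(build_constraint_set(self.GROUPS))
        assert not is_compatible(trees["H-sister+CPfree"],
                                 trees["C-sister+CPfree"])

    def test_missing_groups_rejected(self):
        with pytest.raises(TreeError, match="missing"):
            build_constraint_set({"leptophytes": ["L1"],
                                  "haptophytes": ["H1"]})

    def test_overlapping_groups_rejected(self):
        bad = dict(self.GROUPS)
        bad["red_algae"] = ["R1", "L1"]
        with pytest.raises(TreeError, match="overlap"):
            build_constraint_set(bad)


class TestCompatibility:
    def test_star_constraint_always_satisfied(self):
        assert is_compatible(read_newick("((A,B),(C,D));"),
                             read_newick("(A,B,C,D);"))

    def test_conflicting_split_detected(self):
        assert not is_compatible(read_newick("((A,B),(C,D));"),
                                 read_newick("((A,C),(B,D));"))

    def test_constraint_on_leaf_subset(self):
        big = read_newick("(((A,B),C),((D,E),F));")
        assert is_compatible(big, read_newick("((A,B),(D,E));"))
        assert not is_compatible(big, read_newick("((A,D),(B,E));"))


class TestFastTaxonRemoval:
    def test_zero_is_identity(self):
        t = read_newick("((A:1,B:2):0.5,C:3);")
        pruned, dropped = remove_fastest_taxa(t, 0)
        assert dropped == []
        assert sorted(treeops.leaf_labels(pruned)) == ["A", "B", "C"]

    def test_farthest_leaf_removed(self):
        t = read_newick("((A:1,B:2):0.5,C:3);")
        _, dropped = remove_fastest_taxa(t, 1)
        assert dropped == ["C"]

    def test_ties_broken_lexicographically(self):
        t = read_newick("((A:1,B:1):0.5,C:1.5);")
        _, dropped = remove_fastest_taxa(t, 1)
        assert dropped == ["A"]  # A, B and C all at distance 1.5

    def test_cannot_remove_all(self):
        with pytest.raises(TreeError):
            remove_fastest_taxa(read_newick("(A:1,B:2);"), 2)


class TestUpgma:
    def test_two_taxa_closed_form(self):
        tree = upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        for lf in tree.leaf_node_iter():
            assert lf.edge.length == pytest.approx(2.0)

    def test_three_taxon_hand_agglomeration(self):
        D = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        tree = upgma(D, ["A", "B", "C"])
        g1, g2 = treeops.root_children_partition(tree)
        assert sorted(map(sorted, [g1, g2])) == [["A", "B"], ["C"]]
        depths = {lf.taxon.label: sum(
            e.length for e in (n.edge for n in _path_to_root(lf)))
            for lf in tree.leaf_node_iter()}
        assert depths["C"] == pytest.approx(3.0)

    def test_recovers_ultrametric_tree(self):
        # an ultrametric distance matrix is reproduced exactly
        D = np.array([[0, 2, 8, 8], [2, 0, 8, 8],
                      [8, 8, 0, 4], [8, 8, 4, 0]], float)
        tree = upgma(D, list("ABCD"))
        dist = _cophenetic(tree)
        for (a, b), d in dist.items():
            i, j = "ABCD".index(a), "ABCD".index(b)
            assert d == pytest.approx(D[i, j])

    def test_output_ultrametric(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        tree = upgma(D, [f"t{i}" for i in range(6)])
        depths = [sum(n.edge.length for n in _path_to_root(lf))
                  for lf in tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_asymmetric_rejected(self):
        with pytest.raises(TreeError, match="symmetric"):
            upgma(np.array([[0, 1.0], [2.0, 0]]), ["A", "B"])


def _path_to_root(leaf):
    node = leaf
    while node.parent_node is not None:
        yield node
        node = node.parent_node


def _cophenetic(tree):
    out = {}
    leaves = list(tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    for a, b in itertools.combinations(leaves, 2):
        d = pdm.patristic_distance(a.taxon, b.taxon)
        out[(a.taxon.label, b.taxon.label)] = d
        out[(b.taxon.label, a.taxon.label)] = d
    return out
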