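import numpy as np
import pytest

from divrates import parse_newick
from divrates import pairs as pr
from divrates import trees as trlib

from conftest import tip_depth_map


class TestCollapseToRank:
    def test_singleton_families_unchanged(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        tax = {t: (f"G{t}", f"F{t}") for t in "abc"}
        red = pr.collapse_to_rank(tree, tax, "family")
        assert set(trlib.tip_labels(red)) == {"a", "b", "c"}

    def test_eight_tip_collapse(self, eight_tip_tree, eight_tip_taxonomy):
        """Hand enumeration: keep the first-listed tip of each family and
        sum branch lengths through suppressed nodes."""
        red = pr.collapse_to_rank(
            eight_tip_tree, eight_tip_taxonomy, "family"
        )
        # first tips in written order: F1 -> t1, F2 -> t4, F3 -> t5?
        # written order is t1..t8; F2's first member is t4, F3's is t6
        assert trlib.tip_labels(red) == ["t1", "t4", "t6"]
        # depths are preserved from the original ultrametric tree
        assert tip_depth_map(red) == pytest.approx(
            {"t1": 4.0, "t4": 4.0, "t6": 4.0}
        )

    def test_group_without_data_removed(self, eight_tip_tree,
                                        eight_tip_taxonomy):
        has_data = {"t1", "t2", "t3", "t6", "t7", "t8"}  # F2 has none
        red = pr.collapse_to_rank(
            eight_tip_tree, eight_tip_taxonomy, "family", has_data
        )
        assert trlib.tip_labels(red) == ["t1", "t6"]

    def test_no_data_anywhere_raises(self, eight_tip_tree,
                                     eight_tip_taxonomy):
        with pytest.raises(ValueError):
            pr.collapse_to_rank(
                eight_tip_tree, eight_tip_taxonomy, "family", set()
            )

    def test_representative_is_first_with_data(self, eight_tip_tree,
                                               eight_tip_taxonomy):
        red = pr.collapse_to_rank(
            eight_tip_tree, eight_tip_taxonomy, "family",
            {"t2", "t3", "t4", "t5", "t6"},
        )
        assert trlib.tip_labels(red) == ["t2", "t4", "t6"]


class TestExtractSisterPairs:
    def _pairs(self, nwk, tax=None, rank="family"):
        tree = parse_newick(nwk)
        if tax is None:
            tax = {t: (f"G{t}", f"F{t}")
                   for t in trlib.tip_labels(tree)}
        red = pr.collapse_to_rank(tree, tax, rank)
        return pr.extract_sister_pairs(red, tree, tax, rank)

    def test_caterpillar_single_cherry(self):
        got = self._pairs("(((a:1,b:1):1,c:2):1,d:3);")
        assert len(got) == 1
        assert {got[0].clade_a_tips, got[0].clade_b_tips} == \
            {frozenset({"a"}), frozenset({"b"})}

    def test_balanced_eight_tips_four_cherries(self):
        nwk = ("(((a:1,b:1):1,(c:1,d:1):1):1,"
               "((e:1,f:1):1,(g:1,h:1):1):1);")
        assert len(self._pairs(nwk)) == 4

    def test_two_tip_tree(self):
        assert len(self._pairs("(a:1,b:1);")) == 1

    def test_membership_expanded_to_full_groups(self, eight_tip_tree,
                                                eight_tip_taxonomy):
        red = pr.collapse_to_rank(
            eight_tip_tree, eight_tip_taxonomy, "family"
        )
        pairs = pr.extract_sister_pairs(
            red, eight_tip_tree, eight_tip_taxonomy, "family"
        )
        assert len(pairs) == 1  # reduced tree ((t1,t4),t6): one cherry
        (p,) = pairs
        assert {p.clade_a_tips, p.clade_b_tips} == {
            frozenset({"t1", "t2", "t3"}), frozenset({"t4", "t5"})
        }

    def test_pairs_tip_disjoint_on_random_trees(self, random_tree_factory):
        for seed in range(20):
            tree = random_tree_factory(seed, 24)
            tips = trlib.tip_labels(tree)
            tax = {t: (f"G{i % 9}", f"F{i % 9}")
                   for i, t in enumerate(tips)}
            red = pr.collapse_to_rank(tree, tax, "family")
            pairs = pr.extract_sister_pairs(red, tree, tax, "family")
            seen = set()
            for p in pairs:
                assert not (p.all_tips & seen)
                seen |= p.all_tips


def _make_pair(a_tips, b_tips, rank="family", pid="pair0001"):
    return pr.SisterPair(
        pair_id=pid, rank=rank,
        clade_a_tips=frozenset(a_tips), clade_b_tips=frozenset(b_tips),
    )


class TestMonophylyFilter:
    mono = "(((a1:1,a2:1):1,x1:2):1,((b1:1,b2:1):1,x2:2):1);"
    # x1/x2 are genus GX: inside clade A and clade B respectively
    straddle = "(((a1:1,x1:1):1,a2:2):1,((b1:1,x2:1):1,b2:2):1);"

    tax = {
        "a1": ("GA", "FA"), "a2": ("GA", "FA"),
        "b1": ("GB", "FB"), "b2": ("GB", "FB"),
        "x1": ("GX", "FX"), "x2": ("GX", "FX"),
    }
    mol = {"a1", "a2", "b1", "b2"}

    def _tree_set(self, n_bad, n_total=100):
        bad = parse_newick(self.straddle)
        good = parse_newick(self.mono)
        return [bad] * n_bad + [good] * (n_total - n_bad)

    def _pair(self):
        return _make_pair({"a1", "a2"}, {"b1", "b2"})

    def test_identical_monophyletic_trees_keep_all(self):
        kept, removed = pr.monophyly_filter(
            [self._pair()], self._tree_set(0), self.tax,
            mol_tips=self.mol,
        )
        assert len(kept) == 1 and not removed

    def test_straddling_in_85_of_100_trees_removes(self):
        kept, removed = pr.monophyly_filter(
            [self._pair()], self._tree_set(85), self.tax,
            mol_tips=self.mol,
        )
        assert not kept and len(removed) == 1

    def test_straddling_in_79_of_100_trees_retains(self):
        kept, removed = pr.monophyly_filter(
            [self._pair()], self._tree_set(79), self.tax,
            mol_tips=self.mol,
        )
        assert len(kept) == 1 and not removed

    def test_threshold_is_inclusive_at_80(self):
        kept, removed = pr.monophyly_filter(
            [self._pair()], self._tree_set(80), self.tax,
            mol_tips=self.mol,
        )
        assert not kept and len(removed) == 1

    def test_threshold_one_requires_every_tree(self):
        kept, _ = pr.monophyly_filter(
            [self._pair()], self._tree_set(99), self.tax,
            threshold=1.0, mol_tips=self.mol,
        )
        assert len(kept) == 1
        kept, removed = pr.monophyly_filter(
            [self._pair()], self._tree_set(100), self.tax,
            threshold=1.0, mol_tips=self.mol,
        )
        assert not kept and len(removed) == 1


class TestAverageCladeSizes:
    def test_single_tree_raw_count(self, eight_tip_tree):
        pair = _make_pair({"t1", "t2"}, {"t3", "t4"})
        sa, sb = pr.average_clade_sizes(pair, [eight_tip_tree])
        assert (sa, sb) == (2.0, 2.0)

    def test_two_trees_average_includes_nodata_placements(self):
        """In one tree an extra (no-data) tip sits inside each clade's
        MRCA; sizes average the per-tree descendant counts."""
        t1 = parse_newick(
            "((a1:1,a2:1):2,(b1:1,(b2:0.5,b3:0.5):0.5):2);"
        )
        t2 = parse_newick(
            "((a1:1,(a3:0.5,a2:0.5):0.5):2,(b1:1,b2:1):2);"
        )
        pair = _make_pair({"a1", "a2"}, {"b1", "b2"})
        sa, sb = pr.average_clade_sizes(
            pair, [t1, t2], mol_tips={"a1", "a2", "b1", "b2"}
        )
        assert sa == pytest.approx(2.5)   # counts 2 and 3
        assert sb == pytest.approx(2.5)   # counts 3 and 2

    def test_identical_trees_equal_single_count(self, eight_tip_tree):
        pair = _make_pair({"t5", "t6"}, {"t7", "t8"})
        sa, sb = pr.average_clade_sizes(pair, [eight_tip_tree] * 7)
        assert (sa, sb) == (2.0, 2.0)


class TestBalanceTips:
    def _pair(self, na, nb):
        return _make_pair(
            {f"a{i}" for i in range(na)}, {f"b{i}" for i in range(nb)}
        )

    def test_already_balanced_is_noop(self):
        pair = self._pair(3, 3)
        got = pr.balance_tips(pair, pair.all_tips, rng=0)
        assert got.balanced_a == pair.clade_a_tips
        assert got.balanced_b == pair.clade_b_tips

    def test_five_vs_three(self):
        pair = self._pair(5, 3)
        got = pr.balance_tips(pair, pair.all_tips, rng=1)
        assert len(got.balanced_a) == len(got.balanced_b) == 3
        assert got.balanced_a <= pair.clade_a_tips
        # deterministic given the seed
        again = pr.balance_tips(self._pair(5, 3), pair.all_tips, rng=1)
        assert again.balanced_a == got.balanced_a

    def test_extreme_imbalance(self):
        pair = self._pair(1, 100)
        got = pr.balance_tips(pair, pair.all_tips, rng=2)
        assert len(got.balanced_a) == len(got.balanced_b) == 1

    def test_no_data_clade_dropped(self):
        pair = self._pair(2, 2)
        got = pr.balance_tips(pair, {"a0", "a1"}, rng=0)
        assert got is None


class TestBuildQuartets:
    def test_two_pairs_are_mutual_outgroups(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        tree = parse_newick(nwk)
        tax = {t: (f"G{t}", f"F{t}") for t in "abcd"}
        red = pr.collapse_to_rank(tree, tax, "family")
        pairs = pr.extract_sister_pairs(red, tree, tax, "family")
        quartets = pr.build_quartets(pairs, red)
        assert len(quartets) == 2
        assert quartets[0].outgroup_pair is pairs[1]
        assert quartets[1].outgroup_pair is pairs[0]

    def test_single_pair_raises(self):
        tree = parse_newick("(a:1,b:1);")
        tax = {t: (f"G{t}", f"F{t}") for t in "ab"}
        pairs = [_make_pair({"a"}, {"b"})]
        with pytest.raises(ValueError):
            pr.build_quartets(pairs, tree)

    def test_matches_brute_force_nearest_mrca(self, random_tree_factory):
        """Nearest-neighbour matching agrees with an exhaustive
        patristic-distance search on random instances."""
        for seed in range(12):
            tree = random_tree_factory(seed, 16)
            tips = trlib.tip_labels(tree)
            tax = {t: (f"G{t}", f"F{t}") for t in tips}
            pairs = pr.extract_sister_pairs(tree, tree, tax, "family")
            if len(pairs) < 2:
                continue
            quartets = pr.build_quartets(pairs, tree)
            depths = trlib.node_depths(tree)
            mrcas = [trlib.mrca(tree, p.all_tips) for p in pairs]

            def patristic(u, v):
                anc_u = {}
                nd = u
                while nd is not None:
                    anc_u[id(nd)] = depths[nd]
                    nd = nd.parent_node
                nd = v
                while id(nd) not in anc_u:
                    nd = nd.parent_node
                return (depths[u] - depths[nd]) + (depths[v] - depths[nd])

            for i, q in enumerate(quartets):
                dists = [
                    patristic(mrcas[i], mrcas[j]) if j != i else np.inf
                    for j in range(len(pairs))
                ]
                got = pairs.index(q.outgroup_pair)
                assert dists[got] == pytest.approx(min(dists))
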