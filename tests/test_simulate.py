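import math

import numpy as np
import pytest

from divrates import parse_newick, write_newick
from divrates import trees as trlib
from divrates.simulate import (
    SimConfig,
    assign_taxonomy,
    make_pseudoposterior,
    simulate_tree,
    substitution_branch_lengths,
)


def cfg(**kw):
    base = dict(
        lambda0=0.1, mu=0.0, T=40.0, sigma2=0.0, gamma=0.0, sites=0,
        n_pseudo_trees=0, missing_frac=0.0, min_tips=2, max_tips=5000,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateTree:
    def test_yule_mean_tip_count(self):
        """Pure birth, no rate evolution: mean extant tip count over
        replicates is close to exp(lambda0 * T)."""
        lam, T, n_rep = 0.08, 25.0, 500
        counts = []
        for seed in range(n_rep):
            out = simulate_tree(cfg(lambda0=lam, T=T, min_tips=1,
                                    retry_cap=1, seed=seed))
            counts.append(len(out.time_tree.leaf_nodes()))
        want = math.exp(lam * T)
        # crown-conditioning discards the pre-split stem, which only
        # shortens the tree; the mean count still tracks e^(lam T) from
        # the first lineage, with Yule variance e^x(e^x - 1)
        se = math.sqrt(want * (want - 1) / n_rep)
        assert abs(np.mean(counts) - want) < 4 * se

    def test_no_rate_evolution_gives_constant_rates(self):
        out = simulate_tree(cfg(seed=3))
        for rate in out.branch_rates.values():
            assert rate == pytest.approx(1e-3)

    def test_same_seed_identical_trees(self):
        a = simulate_tree(cfg(sigma2=0.05, seed=11))
        b = simulate_tree(cfg(sigma2=0.05, seed=11))
        assert write_newick(a.time_tree) == write_newick(b.time_tree)
        assert write_newick(a.subs_tree) == write_newick(b.subs_tree)

    def test_time_tree_ultrametric_and_extinct_pruned(self):
        out = simulate_tree(cfg(mu=0.05, T=60, min_tips=10, seed=4))
        assert trlib.is_ultrametric(out.time_tree, rel_tol=1e-6)

    def test_n_tips_stopping_rule(self):
        out = simulate_tree(cfg(T=1e6, n_tips=64, min_tips=10, seed=5))
        assert len(out.time_tree.leaf_nodes()) >= 64

    def test_impossible_config_raises(self):
        with pytest.raises(RuntimeError):
            simulate_tree(cfg(lambda0=1e-6, T=1.0, min_tips=50,
                              retry_cap=3, seed=0))


class TestSubstitutionBranchLengths:
    def test_noise_free_lengths_are_rate_times_time(self):
        out = simulate_tree(cfg(seed=7))
        t_edges = {
            frozenset(trlib.descendant_labels(nd)): nd.edge.length
            for nd in out.time_tree.preorder_node_iter()
            if nd.parent_node is not None
        }
        for nd in out.subs_tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            key = frozenset(trlib.descendant_labels(nd))
            assert nd.edge.length == pytest.approx(1e-3 * t_edges[key])

    def test_poisson_moments(self):
        """A branch with expected 185 substitutions at 2500 sites has
        realized count mean and variance both near 185."""
        tree = parse_newick("(a:0.074,b:0.074);", units="subs/site")
        sites = 2500
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(2000):
            noisy = substitution_branch_lengths(tree, sites, rng)
            counts.append(noisy.leaf_nodes()[0].edge.length * sites)
        counts = np.array(counts)
        assert np.mean(counts) == pytest.approx(185, rel=0.02)
        assert np.var(counts) == pytest.approx(185, rel=0.15)

    def test_doubling_sites_halves_cv(self):
        tree = parse_newick("(a:0.1,b:0.1);", units="subs/site")
        rng = np.random.default_rng(1)

        def cv(sites):
            vals = [
                substitution_branch_lengths(tree, sites, rng)
                .leaf_nodes()[0].edge.length
                for _ in range(3000)
            ]
            return np.std(vals) / np.mean(vals)

        ratio = cv(500) / cv(2000)
        assert ratio == pytest.approx(2.0, rel=0.15)


class TestAssignTaxonomy:
    def test_threshold_above_depth_single_genus(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        tax = assign_taxonomy(tree, genus_age=5, family_age=10)
        assert len({g for g, f in tax.values()}) == 1
        assert len({f for g, f in tax.values()}) == 1

    def test_hand_checked_grouping(self):
        """Six tips with known node ages: genus_age 1.5 splits {a,b},
        {c}, {d,e}, {f}; family_age 3.5 splits {a,b,c} and {d,e,f}."""
        nwk = ("(((a:1,b:1):2,c:3):2,((d:1.2,e:1.2):1.8,f:3):2);")
        tree = parse_newick(nwk)
        tax = assign_taxonomy(tree, genus_age=1.5, family_age=3.5)
        genera = {}
        for tip, (g, f) in tax.items():
            genera.setdefault(g, set()).add(tip)
        assert sorted(map(sorted, genera.values())) == [
            ["a", "b"], ["c"], ["d", "e"], ["f"]
        ]
        fams = {}
        for tip, (g, f) in tax.items():
            fams.setdefault(f, set()).add(tip)
        assert sorted(map(sorted, fams.values())) == [
            ["a", "b", "c"], ["d", "e", "f"]
        ]

    def test_genera_nested_in_families(self):
        out = simulate_tree(cfg(T=80, sigma2=0.0, min_tips=20, seed=9))
        fam_of_genus = {}
        for tip, (g, f) in out.taxonomy.items():
            fam_of_genus.setdefault(g, set()).add(f)
        assert all(len(fams) == 1 for fams in fam_of_genus.values())

    def test_non_ultrametric_rejected(self):
        tree = parse_newick("((a:1,b:2):1,c:2);")
        with pytest.raises(ValueError):
            assign_taxonomy(tree, genus_age=1, family_age=2)


class TestMakePseudoposterior:
    def test_zero_missing_identical_copies(self):
        out = simulate_tree(cfg(T=60, min_tips=10, seed=2))
        trees, mol, nodata = make_pseudoposterior(
            out.time_tree, out.taxonomy, 0.0, 5, np.random.default_rng(0)
        )
        assert len(trees) == 5 and not nodata
        base = write_newick(out.time_tree)
        assert all(write_newick(t) == base for t in trees)

    def test_replicates_stay_ultrametric_with_all_tips(self):
        out = simulate_tree(cfg(T=60, min_tips=20, seed=6))
        n = len(out.time_tree.leaf_nodes())
        trees, mol, nodata = make_pseudoposterior(
            out.time_tree, out.taxonomy, 0.25, 6, np.random.default_rng(1)
        )
        assert len(nodata) == math.ceil(0.25 * n)
        for t in trees:
            assert len(t.leaf_nodes()) == n
            assert trlib.is_ultrametric(t, rel_tol=1e-4)

    def test_family_confined_placement_conserves_family_sizes(self):
        """Re-placing no-data tips inside their family keeps per-family
        tip counts equal to the truth in every replicate."""
        out = simulate_tree(cfg(T=80, min_tips=30, seed=8))
        trees, mol, nodata = make_pseudoposterior(
            out.time_tree, out.taxonomy, 0.2, 5, np.random.default_rng(2)
        )
        fam_members = {}
        for tip, (g, f) in out.taxonomy.items():
            fam_members.setdefault(f, set()).add(tip)
        for fam, members in fam_members.items():
            anchors = members & mol
            if not anchors:
                continue
            for t in trees:
                under = trlib.descendant_labels(trlib.mrca(t, anchors))
                # every true member is inside the family MRCA
                assert members <= under

    def test_displaced_genus_triggers_monophyly_removal(self):
        """A tip forced outside its genus in >= 80% of trees makes the
        affected pair fail the monophyly filter downstream."""
        from divrates import pairs as pr

        nwk = ("(((a1:2,a2:2):4,(b1:2,b2:2):4):4,"
               "((c1:2,c2:2):4,(d1:2,d2:2):4):4);")
        tree = parse_newick(nwk)
        tax = {
            "a1": ("GA", "FA"), "a2": ("GA", "FA"),
            "b1": ("GB", "FB"), "b2": ("GB", "FB"),
            "c1": ("GC", "FC"), "c2": ("GC", "FC"),
            "d1": ("GD", "FD"), "d2": ("GD", "FD"),
        }
        mol = set(tax) - {"a2"}
        pair_ab = pr.SisterPair(
            pair_id="pair0001", rank="family",
            clade_a_tips=frozenset({"a1", "a2"}),
            clade_b_tips=frozenset({"b1", "b2"}),
        )
        # place a2 (genus GA) inside clade B in 9 of 10 trees
        bad = parse_newick(
            "(((a1:2,x:2):4,((b1:2,a2:2):2,b2:4):2):4,"
            "((c1:2,c2:2):4,(d1:2,d2:2):4):4);".replace("x:2", "q:2")
        )
        # rename helper tip q to a throwaway genus
        tax2 = dict(tax)
        tax2["q"] = ("GQ", "FA")
        good = parse_newick(nwk)
        kept, removed = pr.monophyly_filter(
            [pair_ab], [bad] * 9 + [good], tax2, mol_tips=mol,
        )
        assert not kept and len(removed) == 1


class TestTruthRecovery:
    def test_estimated_contrasts_track_truth_in_noise_free_limit(self):
        """Pipeline rate contrasts computed from the noisy subs tree
        correlate strongly (r > 0.9) with those from the noise-free
        expected tree at 10 kb, and match exactly at sites = 0."""
        from divrates import RunConfig
        from divrates.pipeline import run_pipeline, summarize_pair_from_tree
        from divrates import contrasts as ctr

        config = RunConfig(
            rank="family", seed=13, run_tree_test=False,
            apply_monophyly=False, apply_welch=False,
            sim=SimConfig(
                lambda0=0.1, mu=0.05, T=100.0, sigma2=0.05, gamma=0.0,
                sites=10_000, n_pseudo_trees=0, missing_frac=0.0,
                min_tips=60, seed=13,
            ),
        )
        res = run_pipeline(config)
        true_summaries = [
            summarize_pair_from_tree(res.sim.subs_tree_expected, p)
            for p in res.pairs
        ]
        truth = ctr.compute_contrasts(res.pairs, true_summaries)
        merged = res.contrasts.merge(
            truth, on="pair_id", suffixes=("_est", "_true")
        )
        assert len(merged) >= 8
        r = np.corrcoef(
            merged["d_log_rate_est"], merged["d_log_rate_true"]
        )[0, 1]
        assert r > 0.9
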