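"""Tree and table IO: parsing, validation, alignment, cophenetic distances."""

import numpy as np
import pandas as pd
import pytest

import phyloturn as pt
from phyloturn.io import apply_pool_filters, read_community, read_env, read_stage_map
from phyloturn.tree import Phylogeny

from .oracle import dendropy_cophenetic, dendropy_mrca_ages


class TestNewick:
    def test_four_tip_ages(self, four_tip_tree):
        assert four_tip_tree.n_tips == 4
        assert four_tip_tree.root_age == pytest.approx(3.0)
        cherry_ages = sorted(
            rec["age"] for rec in four_tip_tree.nodes if not rec["is_root"]
        )
        assert cherry_ages == pytest.approx([1.0, 1.0])

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            Phylogeny.from_newick("(A:1,B:2);")
        t = Phylogeny.from_newick("(A:1,B:2);", require_ultrametric=False)
        assert not t.is_ultrametric

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Phylogeny.from_newick("((A:1,A:1):1,B:2);")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            Phylogeny.from_newick("((A:1,B:1),C:2);")

    def test_roundtrip_preserves_cophenetic(self, tmp_path):
        tree = pt.simulate_tree(64, seed=5)
        path = tmp_path / "t.nwk"
        path.write_text(tree.write_newick())
        back = pt.read_newick(path)
        assert back.taxa == tree.taxa or set(back.taxa) == set(tree.taxa)
        idx = [back.taxa.index(t) for t in tree.taxa]
        np.testing.assert_allclose(
            back.cophenetic()[np.ix_(idx, idx)], tree.cophenetic(), rtol=1e-9
        )


class TestCophenetic:
    def test_hand_values(self, four_tip_tree):
        D = four_tip_tree.cophenetic()
        i = {n: k for k, n in enumerate(four_tip_tree.taxa)}
        assert D[i["A"], i["B"]] == pytest.approx(2.0)
        assert D[i["A"], i["C"]] == pytest.approx(6.0)
        assert D[i["C"], i["D"]] == pytest.approx(2.0)

    def test_star_tree(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        D = star.cophenetic()
        off = D[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 2.0)

    def test_matches_dendropy_on_random_tree(self):
        tree = pt.simulate_tree(32, seed=9)
        np.testing.assert_allclose(
            tree.cophenetic(), dendropy_cophenetic(tree), rtol=1e-9, atol=1e-9
        )

    def test_distance_equals_twice_mrca_age(self):
        tree = pt.simulate_tree(32, seed=10)
        ages = dendropy_mrca_ages(tree)
        np.testing.assert_allclose(tree.cophenetic(), 2 * ages, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(tree.mrca_ages(), ages, rtol=1e-8, atol=1e-8)

    def test_symmetry_zero_diagonal_three_point(self):
        tree = pt.simulate_tree(24, seed=11)
        D = tree.cophenetic()
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)
        rng = np.random.default_rng(0)
        for _ in range(200):  # ultrametric three-point condition
            i, j, k = rng.choice(24, 3, replace=False)
            a, b, c = sorted([D[i, j], D[i, k], D[j, k]])
            assert b == pytest.approx(c, rel=1e-6)

    def test_prune_then_cophenetic_equals_subset(self):
        tree = pt.simulate_tree(40, seed=12)
        rng = np.random.default_rng(1)
        keep = [tree.taxa[i] for i in rng.choice(40, 15, replace=False)]
        sub = tree.prune_to(keep)
        idx = tree.index_of(sub.taxa)
        np.testing.assert_allclose(
            sub.cophenetic(), tree.cophenetic()[np.ix_(idx, idx)], rtol=1e-9
        )


class TestPoolFilters:
    def test_exclusion_and_report(self):
        pool = pt.simulate_tree(10, seed=1)
        pruned, report = apply_pool_filters(
            pool, {"ruleA": [pool.taxa[0], pool.taxa[3]]}
        )
        assert pruned.n_tips == 8
        assert report["ruleA"] == [pool.taxa[0], pool.taxa[3]]
        assert pruned.is_ultrametric

    def test_empty_exclusion_is_identity(self):
        pool = pt.simulate_tree(10, seed=2)
        pruned, report = apply_pool_filters(pool, {"a": [], "b": []})
        assert pruned is pool
        assert all(v == [] for v in report.values())

    def test_three_rules_438_to_410(self):
        pool = pt.simulate_tree(438, seed=3)
        taxa = list(pool.taxa)
        rules = {
            "nonangiosperm": taxa[:20],
            "bamboo": taxa[20:21],
            "cultivated": taxa[21:28],
        }
        pruned, report = apply_pool_filters(pool, rules)
        assert pruned.n_tips == 410
        assert sum(len(v) for v in report.values()) == 28

    def test_unknown_name_warns_not_errors(self, caplog):
        pool = pt.simulate_tree(10, seed=4)
        pruned, report = apply_pool_filters(pool, {"r": ["NotASpecies"]})
        assert pruned.n_tips == 10
        assert report["r"] == []


class TestTables:
    def test_community_roundtrip_and_sums(self, tmp_path):
        df = pd.DataFrame(
            [[0, 2, 3], [5, 1, 1]], index=["p1", "p2"], columns=["A", "B", "C"]
        )
        path = tmp_path / "c.tsv"
        df.to_csv(path, sep="\t")
        back = read_community(path)
        assert list(back.sum(axis=1)) == [5, 7]
        pd.testing.assert_frame_equal(back, df.astype(np.int64))

    def test_community_rejects_noninteger_and_negative(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("plot\tA\tB\np1\t1.5\t2\n")
        with pytest.raises(ValueError, match="integer"):
            read_community(p)
        p.write_text("plot\tA\tB\np1\t-1\t2\n")
        with pytest.raises(ValueError, match="negative"):
            read_community(p)

    def test_stage_map_sizes(self, tmp_path):
        rows = ["plot\tstage"]
        sizes = (5, 4, 5, 6, 7)
        k = 0
        for s, n in enumerate(sizes, 1):
            for _ in range(n):
                k += 1
                rows.append(f"P{k:02d}\t{s}")
        p = tmp_path / "s.tsv"
        p.write_text("\n".join(rows) + "\n")
        stages = read_stage_map(p)
        assert tuple(stages.value_counts().sort_index()) == sizes
        assert stages.cat.ordered

    def test_env_requires_coordinates(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("plot\tpH\tmoisture\np1\t4.5\t0.2\n")
        with pytest.raises(ValueError, match="coordinate"):
            read_env(p)

    def test_csv_autodetected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("plot,A,B\np1,1,2\np2,3,4\n")
        assert read_community(p).shape == (2, 2)


class TestAlign:
    def test_align_prunes_and_orders(self, pool64):
        species = list(pool64.taxa[:10])
        community = pd.DataFrame(
            np.ones((3, 10), dtype=int), index=["p1", "p2", "p3"], columns=species
        )
        stages = pd.Series(["1", "1", "2"], index=community.index)
        b = pt.align_and_prune(pool64, community, stages)
        assert b.tree.n_tips == 10
        assert list(b.community.columns) == list(b.tree.taxa)
        np.testing.assert_allclose(b.community_distances(), b.D, rtol=1e-9)

    def test_align_all_species_equals_pool(self, pool64):
        community = pd.DataFrame(
            np.ones((2, 64), dtype=int), index=["p1", "p2"], columns=list(pool64.taxa)
        )
        stages = pd.Series(["1", "1"], index=community.index)
        b = pt.align_and_prune(pool64, community, stages)
        assert b.tree.n_tips == pool64.n_tips
        np.testing.assert_allclose(b.tree.cophenetic(), pool64.cophenetic())

    def test_unknown_species_named_in_error(self, pool64):
        community = pd.DataFrame(
            [[1, 1]], index=["p1"], columns=[pool64.taxa[0], "Ghost_species"]
        )
        stages = pd.Series(["1"], index=["p1"])
        with pytest.raises(KeyError, match="Ghost_species"):
            pt.align_and_prune(pool64, community, stages)

    def test_missing_stage_errors(self, pool64):
        community = pd.DataFrame(
            [[1, 1], [1, 1]], index=["p1", "p2"], columns=list(pool64.taxa[:2])
        )
        stages = pd.Series(["1"], index=["p1"])
        with pytest.raises(ValueError, match="p2"):
            pt.align_and_prune(pool64, community, stages)

    def test_underscore_space_normalization(self):
        tree = pt.Phylogeny.from_newick("((Abies_alba:1,B:1):2,(C:1,D:1):2);")
        community = pd.DataFrame(
            [[1, 1], [1, 1]], index=["p1", "p2"], columns=["Abies alba", "B"]
        )
        stages = pd.Series(["1", "1"], index=community.index)
        b = pt.align_and_prune(tree, community, stages)
        assert "Abies_alba" in b.species
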