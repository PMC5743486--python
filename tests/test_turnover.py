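"""Turnover statistics: hand examples, brute-force oracle, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phyloturn as pt
from phyloturn.turnover import (
    alpha_within,
    beta_between,
    evenness,
    grouped_turnover,
    pair_deltas,
    pairwise_turnover,
    pooled_statistic,
    turnover_matrix,
)

from .conftest import small_bundle
from .oracle import brute_alpha, brute_beta, brute_pair_statistic
from .conftest import random_instance


def idx_counts(tree, presence):
    """Counts row from a list of present species names."""
    row = np.zeros(tree.n_tips)
    row[tree.index_of(presence)] = 1
    return row


class TestAlphaWithin:
    def test_single_pair(self, four_tip_tree):
        row = idx_counts(four_tip_tree, ["A", "B"])
        assert alpha_within(row, four_tip_tree.cophenetic(), "presence") == pytest.approx(2.0)

    def test_all_four_equal_abundance(self, four_tip_tree):
        row = np.ones(4)
        D = four_tip_tree.cophenetic()
        expected = (2 + 2 + 4 * 6) / 6  # 28/6 over the six unordered pairs
        assert alpha_within(row, D, "presence") == pytest.approx(expected)
        assert alpha_within(row, D, "abundance") == pytest.approx(expected)

    def test_skewed_two_species_weights_cancel(self, four_tip_tree):
        row = np.zeros(4)
        i = {n: k for k, n in enumerate(four_tip_tree.taxa)}
        row[i["A"]], row[i["B"]] = 9, 1
        assert alpha_within(row, four_tip_tree.cophenetic(), "abundance") == pytest.approx(2.0)

    def test_singleton_flagged_nan(self, four_tip_tree):
        row = idx_counts(four_tip_tree, ["A"])
        assert np.isnan(alpha_within(row, four_tip_tree.cophenetic(), "presence"))


class TestBetaBetween:
    def test_disjoint_plots(self, four_tip_tree):
        D = four_tip_tree.cophenetic()
        k = idx_counts(four_tip_tree, ["A", "B"])
        l = idx_counts(four_tip_tree, ["C", "D"])
        assert beta_between(k, l, D, "presence") == pytest.approx(6.0)

    def test_identical_plots_give_zero_statistic(self, four_tip_tree):
        D = four_tip_tree.cophenetic()
        k = idx_counts(four_tip_tree, ["A", "B"])
        da = beta_between(k, k, D, "presence")
        assert da == pytest.approx(2.0)  # cross pairs (A,B) and (B,A) only
        stat = turnover_matrix(np.vstack([k, k]), D, "presence")
        assert stat[0, 1] == pytest.approx(0.0)

    def test_star_tree_statistic_zero(self):
        star = pt.Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        D = star.cophenetic()
        counts = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        stat = turnover_matrix(counts, D, "presence")
        assert stat[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_shared_species_only_is_undefined(self, four_tip_tree):
        D = four_tip_tree.cophenetic()
        k = idx_counts(four_tip_tree, ["A"])
        assert np.isnan(beta_between(k, k, D, "presence"))


class TestPairwiseTurnover:
    def test_two_plot_example(self, four_tip_bundle):
        pairs = pairwise_turnover(four_tip_bundle, "presence")
        assert len(pairs) == 1
        assert pairs.loc[0, "statistic"] == pytest.approx(1 - 2 / 6)

    def test_combinatorics_27_plots(self, neutral_bundle):
        pairs = pairwise_turnover(neutral_bundle, "presence")
        assert len(pairs) == 351
        assert (pairs["group"] == "within").sum() == 62
        assert (pairs["group"] == "between").sum() == 289

    @pytest.mark.parametrize("mode", ["presence", "abundance"])
    def test_matches_bruteforce_oracle(self, mode):
        rng = np.random.default_rng(2024)
        for _ in range(8):
            tree, counts = random_instance(rng)
            D = tree.cophenetic()
            dw, da = pair_deltas(counts, D, mode)
            stat = turnover_matrix(counts, D, mode)
            for k in range(counts.shape[0]):
                ref = brute_alpha(counts[k], D, mode)
                if np.isnan(ref):
                    assert np.isnan(dw[k])
                else:
                    assert dw[k] == pytest.approx(ref, abs=1e-12)
                for l in range(k + 1, counts.shape[0]):
                    ref_b = brute_beta(counts[k], counts[l], D, mode)
                    ref_s = brute_pair_statistic(counts[k], counts[l], D, mode)
                    if np.isnan(ref_b):
                        assert np.isnan(da[k, l])
                    else:
                        assert da[k, l] == pytest.approx(ref_b, abs=1e-12)
                    if np.isnan(ref_s):
                        assert np.isnan(stat[k, l])
                    else:
                        assert stat[k, l] == pytest.approx(ref_s, abs=1e-12)


class TestGrouped:
    def test_within_stage_pair_counts(self, neutral_bundle):
        pairs = pairwise_turnover(neutral_bundle, "presence")
        counts = (
            pairs[pairs["group"] == "within"].groupby("stage_pair").size().sort_index()
        )
        assert list(counts) == [10, 6, 10, 15, 21]

    def test_identical_plots_all_zero(self, four_tip_tree):
        b = small_bundle(
            four_tip_tree,
            {"p1": {"A": 1, "B": 1}, "p2": {"A": 1, "B": 1}, "p3": {"A": 1, "B": 1}},
            {"p1": 1, "p2": 1, "p3": 1},
        )
        pairs = pairwise_turnover(b, "presence")
        grouped = grouped_turnover(pairs, "presence")
        overall = grouped[grouped["grouping"] == "overall"].iloc[0]
        assert overall["mean"] == pytest.approx(0.0, abs=1e-12)
        assert overall["se"] == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_group_mean_equals_value(self, four_tip_bundle):
        pairs = pairwise_turnover(four_tip_bundle, "presence")
        grouped = grouped_turnover(pairs, "presence")
        row = grouped[grouped["grouping"] == "stage"].iloc[0]
        assert row["mean"] == pytest.approx(pairs.loc[0, "statistic"])
        assert row["n_pairs"] == 1

    def test_pooled_convention_by_enumeration(self):
        tree = pt.simulate_tree(6, seed=42)
        rng = np.random.default_rng(3)
        counts = {
            f"p{k}": {tree.taxa[i]: int(c) for i, c in
                      enumerate(rng.integers(1, 5, 6))}
            for k in range(4)
        }
        b = small_bundle(tree, counts, {"p0": 1, "p1": 1, "p2": 2, "p3": 2})
        pairs = pairwise_turnover(b, "presence")
        within = pairs[pairs["group"] == "within"]
        # exhaustive reference for the pooled ratio
        D = b.D
        dws, das = [], []
        for _, row in within.iterrows():
            das.append(brute_beta(b.community.loc[row.plot_i].to_numpy(),
                                  b.community.loc[row.plot_j].to_numpy(),
                                  D, "presence"))
        for p in b.plots:
            dws.append(brute_alpha(b.community.loc[p].to_numpy(), D, "presence"))
        expected = 1 - np.mean(dws) / np.mean(das)
        assert pooled_statistic(within) == pytest.approx(expected, abs=1e-12)


class TestInvariants:
    def test_presence_equals_abundance_for_equal_counts(self, pool64):
        rng = np.random.default_rng(5)
        counts = (rng.random((4, 64)) < 0.3).astype(float)
        counts[:, :2] = 1
        D = pool64.cophenetic()
        np.testing.assert_allclose(
            turnover_matrix(counts, D, "presence"),
            turnover_matrix(counts, D, "abundance"),
            rtol=1e-10,
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0), seed=st.integers(0, 1000))
    def test_branch_scaling_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        tree, counts = random_instance(rng, n_species=6, n_plots=3)
        D = tree.cophenetic()
        s1 = turnover_matrix(counts, D, "presence")
        s2 = turnover_matrix(counts, D * scale, "presence")
        np.testing.assert_allclose(s1, s2, rtol=1e-9, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_statistic_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        tree, counts = random_instance(rng)
        for mode in ("presence", "abundance"):
            stat = turnover_matrix(counts, tree.cophenetic(), mode)
            vals = stat[np.isfinite(stat)]
            assert np.all(vals <= 1.0 + 1e-12)


class TestEvenness:
    def test_equal_counts_maximal(self):
        assert evenness([5, 5, 5, 5]) == pytest.approx(1.0)

    def test_skewed_counts(self):
        f = np.array([97, 1, 1, 1]) / 100
        H = -np.sum(f * np.log(f))
        assert evenness([97, 1, 1, 1]) == pytest.approx(H / np.log(4))
        assert evenness([97, 1, 1, 1]) < 0.2

    def test_single_species_flagged_zero(self):
        assert evenness([10]) == 0.0

    def test_empty_plot_errors(self):
        with pytest.raises(ValueError):
            evenness([0, 0])
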