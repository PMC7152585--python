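import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organedit.editing_caller import EditingSite
from organedit.efficiency_analysis import (
    EfficiencyMatrix,
    TrendRule,
    build_efficiency_matrix,
    call_trends,
    classify_trend,
    editing_efficiency,
    hierarchical_cluster,
    neighbor_condition_comparisons,
    normalize_rows,
    site_condition_test,
    wilcoxon_rank_sum,
)
from organedit.errors import DataError, PreconditionError

from .oracles import (
    complete_linkage_oracle,
    fisher_two_sided_oracle,
    rank_sum_exact_oracle,
    scipy_tree_merges,
)


def _site(site_id, cond, edited, total):
    return EditingSite(
        site_id=site_id, seq_id="m", pos=int(site_id.split("-")[1]),
        ref_allele="C", alt_allele="T", gene_id="g", region="CDS",
        edit_type="C-to-U", edited_depth=edited, total_depth=total,
        condition_id=cond,
    )


class TestEditingEfficiency:
    @pytest.mark.parametrize("edited,total,expected", [
        (0, 20, 0.0), (20, 20, 1.0), (12, 20, 0.6),
    ])
    def test_fraction(self, edited, total, expected):
        assert editing_efficiency(edited, total) == pytest.approx(expected)

    def test_uncovered_site_is_missing(self):
        assert np.isnan(editing_efficiency(0, 0))

    def test_impossible_depths_rejected(self):
        with pytest.raises(DataError):
            editing_efficiency(21, 20)


class TestBuildMatrix:
    def test_union_semantics_with_missing_cells(self):
        conds = ["T25", "T35", "T40", "T45"]
        sites = {c: [_site("m-1", c, 5, 10)] for c in conds}
        sites["T25"] += [_site("m-2", "T25", 3, 10), _site("m-3", "T25", 4, 10)]
        m = build_efficiency_matrix(sites, conds)
        assert m.efficiency.shape == (3, 4)
        assert int(m.efficiency.isna().sum().sum()) == 6

    def test_identical_site_sets_have_no_missing_cells(self):
        conds = ["T25", "T35"]
        sites = {c: [_site("m-1", c, 5, 10), _site("m-2", c, 2, 10)] for c in conds}
        assert not build_efficiency_matrix(sites, conds).efficiency.isna().any().any()

    def test_duplicate_site_in_condition_rejected(self):
        sites = {"T25": [_site("m-1", "T25", 5, 10), _site("m-1", "T25", 5, 10)]}
        with pytest.raises(DataError, match="duplicate"):
            build_efficiency_matrix(sites, ["T25"])

    def test_empty_condition_warns(self):
        sites = {"T25": [_site("m-1", "T25", 5, 10)], "T35": []}
        with pytest.warns(UserWarning, match="T35"):
            m = build_efficiency_matrix(sites, ["T25", "T35"])
        assert m.efficiency["T35"].isna().all()

    def test_frame_roundtrip(self):
        conds = ["T25", "T35"]
        sites = {c: [_site("m-1", c, 5, 10)] for c in conds}
        m = build_efficiency_matrix(sites, conds)
        rt = EfficiencyMatrix.from_frame(m.to_frame())
        pd.testing.assert_frame_equal(rt.edited, m.edited)
        pd.testing.assert_frame_equal(rt.total, m.total)


class TestSiteConditionTest:
    def test_identical_proportions(self):
        assert site_condition_test(10, 20, 10, 20) == pytest.approx(1.0)

    def test_fully_separated(self):
        assert site_condition_test(10, 10, 0, 10) == pytest.approx(2 / 184756,
                                                                   rel=1e-9)

    def test_matches_enumeration_oracle(self):
        assert site_condition_test(8, 20, 3, 20) == pytest.approx(
            fisher_two_sided_oracle(8, 12, 3, 17), rel=1e-9
        )

    def test_zero_total_rejected(self):
        with pytest.raises(PreconditionError):
            site_condition_test(0, 0, 5, 10)


class TestClassifyTrend:
    @pytest.mark.parametrize("effs,label", [
        ((0.9, 0.7, 0.5, 0.3), "step_down"),
        ((0.2, 0.4, 0.6, 0.9), "step_up"),
        ((0.5, 0.6, 0.4, 0.7), "none"),
        ((0.5, 0.5, 0.4, 0.3), "none"),
        ((0.9, float("nan"), 0.5, 0.3), "incomplete"),
    ])
    def test_labels(self, effs, label):
        assert classify_trend(effs) == label

    def test_single_condition_rejected(self):
        with pytest.raises(PreconditionError):
            classify_trend([0.5])


class TestWilcoxon:
    def test_exact_extreme_ordering(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(rank_sum_exact_oracle([1, 2, 3], [4, 5, 6]))

    def test_identical_multisets_give_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_all_ties_degenerate_variance_guard(self):
        _, p = wilcoxon_rank_sum([0.5] * 10, [0.5] * 10)
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(PreconditionError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_and_approximate_agree_for_small_groups(self):
        """Tie-free groups of sizes 7-8: branches agree within 0.02 in p."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            na, nb = rng.integers(7, 9, size=2)
            pooled = rng.permutation(rng.uniform(0, 1, size=na + nb))
            a, b = pooled[:na], pooled[na:]
            from scipy.stats import mannwhitneyu
            _, p_exact = wilcoxon_rank_sum(a, b)  # takes the exact branch
            p_approx = mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic",
                                    use_continuity=True).pvalue
            assert abs(p_exact - p_approx) <= 0.02


class TestNeighborComparisons:
    def test_planted_step_down_sites_all_significant(self, study):
        ds, result = study
        truth_down = set(
            ds.truth_sites[ds.truth_sites.trend == "step_down"].site_id
        )
        subset = [s for s in result.matrix.site_ids if s in truth_down]
        table = neighbor_condition_comparisons(result.matrix, subset)
        assert table["significant"].all()

    def test_flat_sites_not_significant(self, study):
        ds, result = study
        flat = set(ds.truth_sites[ds.truth_sites.trend == "flat"].site_id)
        subset = [s for s in result.matrix.site_ids if s in flat]
        table = neighbor_condition_comparisons(result.matrix, subset)
        assert not table["significant"].any()

    def test_single_site_has_no_power(self, study):
        _, result = study
        table = neighbor_condition_comparisons(result.matrix,
                                               [result.matrix.site_ids[0]])
        assert not table["significant"].any()
        assert table["p"].notna().all()

    def test_empty_subset_rejected(self, study):
        _, result = study
        with pytest.raises(PreconditionError):
            neighbor_condition_comparisons(result.matrix, [])


class TestTrendCalling:
    def _matrix(self, edited_rows, total=100):
        conds = ["T25", "T35", "T40", "T45"]
        edited = pd.DataFrame(edited_rows, columns=conds,
                              index=[f"m-{i}" for i in range(len(edited_rows))],
                              dtype=float)
        totals = pd.DataFrame(total, columns=conds, index=edited.index,
                              dtype=float)
        return EfficiencyMatrix(edited=edited, total=totals)

    def test_default_rule_requires_endpoint_significance(self):
        m = self._matrix([[52, 51, 50, 49]])  # monotone but negligible change
        (call,) = call_trends(m)
        assert call.trend == "none"
        assert call.endpoint_p is not None and call.endpoint_p >= 0.01

    def test_strong_decline_called_step_down(self):
        m = self._matrix([[90, 70, 50, 30]])
        (call,) = call_trends(m)
        assert call.trend == "step_down"
        assert call.endpoint_p < 0.01
        assert len(call.neighbor_p) == 3

    def test_monotone_only_rule_accepts_weak_decline(self):
        m = self._matrix([[52, 51, 50, 49]])
        (call,) = call_trends(m, TrendRule(significance_alpha=None))
        assert call.trend == "step_down"

    def test_nonstrict_rule_allows_plateau_with_total_drop(self):
        m = self._matrix([[90, 60, 60, 30]])
        (strict_call,) = call_trends(m)
        assert strict_call.trend == "none"
        (call,) = call_trends(
            m, TrendRule(monotone="nonstrict", min_total_change=0.2)
        )
        assert call.trend == "step_down"

    def test_missing_condition_is_incomplete(self):
        m = self._matrix([[90, 70, 50, 30]])
        m.total.iloc[0, 1] = float("nan")
        m.edited.iloc[0, 1] = float("nan")
        (call,) = call_trends(m)
        assert call.trend == "incomplete"


class TestNormalizeRows:
    def test_centering_and_sample_sd(self):
        out = normalize_rows(np.array([[1.0, 2.0, 3.0]]))
        assert out[0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zero(self):
        out = normalize_rows(np.array([[0.4, 0.4, 0.4, 0.4]]))
        assert out[0] == pytest.approx([0.0, 0.0, 0.0, 0.0])

    def test_two_point_row(self):
        out = normalize_rows(np.array([[0.0, 1.0]]))
        assert out[0] == pytest.approx([-0.70710678, 0.70710678])

    def test_missing_cells_imputed_with_row_mean(self):
        out = normalize_rows(np.array([[0.0, np.nan, 1.0]]))
        assert out[0][1] == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4),
        min_size=1, max_size=6,
    ))
    def test_rows_have_zero_mean_unit_sd_or_all_zero(self, rows):
        out = normalize_rows(np.array(rows))
        for row in out:
            assert abs(row.mean()) < 1e-9
            sd = row.std(ddof=1)
            assert sd == pytest.approx(1.0, abs=1e-9) or row == pytest.approx(0.0)


class TestHierarchicalCluster:
    def test_nearest_points_merge_first(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.1], [5.0, 5.0]])
        order, tree = hierarchical_cluster(pts)
        assert sorted(tree[0][:2].astype(int)) == [0, 1]
        assert set(order) == {0, 1, 2}

    def test_duplicate_rows_merge_at_height_zero(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 0.0]])
        _, tree = hierarchical_cluster(pts)
        assert tree[0][2] == 0.0

    def test_single_item_identity(self):
        order, tree = hierarchical_cluster(np.array([[1.0, 2.0]]))
        assert order == [0] and tree.shape == (0, 4)

    def test_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 1, size=(6, 4))
        _, tree = hierarchical_cluster(pts)
        got = scipy_tree_merges(tree, 6)
        expected = complete_linkage_oracle(pts)
        assert len(got) == len(expected)
        for (set_a, h_a), (set_b, h_b) in zip(
            sorted(got, key=lambda m: m[1]), sorted(expected, key=lambda m: m[1])
        ):
            assert set_a == set_b
            assert h_a == pytest.approx(h_b, rel=1e-9)

    def test_merge_structure_invariant_under_row_permutation(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, size=(7, 3))
        perm = rng.permutation(7)
        _, tree_orig = hierarchical_cluster(pts)
        _, tree_perm = hierarchical_cluster(pts[perm])
        orig = {
            (frozenset(members), round(h, 12))
            for members, h in scipy_tree_merges(tree_orig, 7)
        }
        back = {
            (frozenset(int(perm[i]) for i in members), round(h, 12))
            for members, h in scipy_tree_merges(tree_perm, 7)
        }
        assert orig == back

    def test_sample_axis_clusters_conditions(self, study):
        _, result = study
        normed = normalize_rows(result.matrix.efficiency)
        order, tree = hierarchical_cluster(normed, axis="cols")
        assert sorted(order) == [0, 1, 2, 3]
        assert tree.shape == (3, 4)
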