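"""Pair enumeration, Spearman concordance, BH adjustment, rank-sum test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cohortsig import (ComparisonPair, ValidationError, bh_adjust,
                       cluster_signature, concordance_analysis,
                       concordance_summary, correlate_pair, enumerate_pairs,
                       wilcoxon_rank_sum)
from cohortsig.concordance import (ConcordanceResult, adjust_results,
                                   spearman_t_pvalue)


def sig_frame(study, timepoint, values, features=None):
    features = features or [f"F{i}" for i in range(len(values))]
    return pd.DataFrame({
        "study_id": study, "feature_id": features,
        "timepoint_months": float(timepoint), "signed_log10p": values,
    })


class TestEnumeratePairs:
    def test_four_study_example_counts(self):
        tp_map = {"BS": {1, 6}, "Assal": {3, 12, 24}, "Afshar": {6},
                  "Ilhan": {6, 12}}
        pairs = enumerate_pairs(tp_map)
        between = [p for p in pairs if p.kind == "between"]
        within = [p for p in pairs if p.kind == "within"]
        assert len(between) == 23
        assert len(within) == 5

    def test_two_studies_single_timepoints(self):
        pairs = enumerate_pairs({"A": {6}, "B": {6}})
        assert len(pairs) == 1
        assert pairs[0].kind == "between"

    def test_single_study_single_timepoint_gives_no_pairs(self):
        assert enumerate_pairs({"A": {6}}) == []

    def test_single_study_three_timepoints(self):
        pairs = enumerate_pairs({"A": {1, 6, 12}})
        assert len(pairs) == 3
        assert all(p.kind == "within" for p in pairs)

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            enumerate_pairs({})

    def test_non_positive_timepoint_rejected(self):
        with pytest.raises(ValidationError, match="> 0"):
            enumerate_pairs({"A": {0, 6}})

    def test_deterministic_lexicographic_order(self):
        pairs = enumerate_pairs({"B": {1, 2}, "A": {3}})
        assert [(p.study_a, p.timepoint_a, p.study_b, p.timepoint_b) for p in pairs] == [
            ("A", 3, "B", 1), ("A", 3, "B", 2), ("B", 1, "B", 2),
        ]

    @given(st.dictionaries(st.sampled_from(["A", "B", "C", "D"]),
                           st.sets(st.sampled_from([1.0, 3.0, 6.0, 12.0]),
                                   min_size=1, max_size=4),
                           min_size=1, max_size=4))
    def test_counts_match_combinatorics(self, tp_map):
        pairs = enumerate_pairs(tp_map)
        studies = sorted(tp_map)
        n_between = sum(len(tp_map[a]) * len(tp_map[b])
                        for a, b in itertools.combinations(studies, 2))
        n_within = sum(len(t) * (len(t) - 1) // 2 for t in tp_map.values())
        assert sum(p.kind == "between" for p in pairs) == n_between
        assert sum(p.kind == "within" for p in pairs) == n_within


class TestCorrelatePair:
    def pair(self):
        return ComparisonPair("A", 1.0, "B", 6.0, "between")

    def test_monotone_signatures_give_rho_one(self):
        a = sig_frame("A", 1, [0.1, 1.0, 2.0, 3.5])
        b = sig_frame("B", 6, [1.0, 2.0, 8.0, 9.0])
        r = correlate_pair(a, b, self.pair())
        assert r.rho == pytest.approx(1.0)
        assert r.n_shared == 4

    def test_reversed_signatures_give_minus_one(self):
        a = sig_frame("A", 1, [1.0, 2.0, 3.0, 4.0])
        b = sig_frame("B", 6, [4.0, 3.0, 2.0, 1.0])
        assert correlate_pair(a, b, self.pair()).rho == pytest.approx(-1.0)

    def test_shared_features_are_the_intersection(self):
        a = sig_frame("A", 1, [1.0, 2.0, 3.0, 4.0, 5.0],
                      ["F1", "F2", "F3", "F4", "F5"])
        b = sig_frame("B", 6, [1.0, 2.0, 3.0, 4.0, 5.0],
                      ["F3", "F4", "F5", "F6", "F7"])
        assert correlate_pair(a, b, self.pair()).n_shared == 3

    def test_missing_values_dropped_pairwise(self):
        a = sig_frame("A", 1, [1.0, np.nan, 3.0, 4.0, 5.0])
        b = sig_frame("B", 6, [1.0, 2.0, 3.0, 4.0, np.nan])
        assert correlate_pair(a, b, self.pair()).n_shared == 3

    def test_too_few_shared_features_flagged_not_raised(self):
        a = sig_frame("A", 1, [1.0, 2.0], ["F1", "F2"])
        b = sig_frame("B", 6, [1.0, 2.0], ["F2", "F3"])
        r = correlate_pair(a, b, self.pair())
        assert r.n_shared == 1
        assert math.isnan(r.rho)
        assert not r.valid

    def test_symmetry_in_pair_orientation(self):
        rng = np.random.default_rng(6)
        a = sig_frame("A", 1, rng.normal(size=20))
        b = sig_frame("B", 6, rng.normal(size=20))
        fwd = correlate_pair(a, b, ComparisonPair("A", 1.0, "B", 6.0, "between"))
        rev = correlate_pair(b, a, ComparisonPair("B", 6.0, "A", 1.0, "between"))
        assert fwd.rho == pytest.approx(rev.rho, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        a = sig_frame("A", 1, x)
        b1 = sig_frame("B", 6, rng.normal(size=30))
        b2 = sig_frame("B", 6, np.exp(b1["signed_log10p"].to_numpy()))
        r1 = correlate_pair(a, b1, self.pair())
        r2 = correlate_pair(a, b2, self.pair())
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)

    def test_missing_contrast_rejected(self):
        a = sig_frame("A", 1, [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError, match="no signature rows"):
            correlate_pair(a, a, ComparisonPair("A", 1.0, "Z", 6.0, "between"))


class TestSpearmanP:
    def test_matches_t_distribution_formula(self):
        rho, n = 0.5, 20
        t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
        expect = 2 * stats.t.sf(abs(t), n - 2)
        assert spearman_t_pvalue(rho, n) == pytest.approx(expect, rel=1e-12)

    def test_perfect_correlation_has_positive_floor_p(self):
        p = spearman_t_pvalue(1.0, 10)
        assert 0 < p < 1e-300


class TestBhAdjust:
    def test_hand_example_equal_q(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_hand_example_mixed(self):
        np.testing.assert_allclose(bh_adjust([0.005, 0.04, 0.8]),
                                   [0.015, 0.06, 0.8])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_empty_input(self):
        assert bh_adjust([]) == []

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [np.nan]):
            with pytest.raises(ValidationError):
                bh_adjust(bad)

    def test_order_preserved(self):
        p = [0.8, 0.005, 0.04]
        np.testing.assert_allclose(bh_adjust(p), [0.8, 0.015, 0.06])

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_statsmodels_and_dominates_p(self, p):
        from statsmodels.stats.multitest import multipletests

        q = np.array(bh_adjust(p))
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        assert (q >= np.array(p) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()


def rank_sum_exact_p(x, y):
    """Brute-force exact two-sided rank-sum p by enumerating group assignments."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(combined) + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


class TestWilcoxonRankSum:
    def test_hand_example(self):
        # {1,2} vs {3,4}: only the observed split is as extreme on each side
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_statistic_is_rank_sum_of_first_sample(self):
        w, _ = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 3.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(1.0, 8.0))[:3]
        y = np.setdiff1d(np.arange(1.0, 8.0), x)[:4]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(rank_sum_exact_p(x, y), abs=1e-9)

    def test_asymptotic_branch_close_to_exact_for_moderate_n(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 25)  # > 20 forces the normal approximation
        y = rng.normal(0.8, 1, 25)
        _, p_asym = wilcoxon_rank_sum(x, y)
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
        assert p_asym == pytest.approx(p_exact, rel=0.15)

    def test_ties_handled_via_correction(self):
        x = [1.0, 1.0, 2.0, 2.0, 3.0]
        y = [2.0, 3.0, 3.0, 4.0, 4.0]
        _, p = wilcoxon_rank_sum(x, y)
        assert 0 < p <= 1


class TestSummaryAndAdjust:
    def _results(self, between, within):
        out = []
        for i, rho in enumerate(between):
            out.append(ConcordanceResult(
                ComparisonPair("A", 1.0, "B", float(i + 1), "between"),
                rho, spearman_t_pvalue(rho, 50), 50))
        for i, rho in enumerate(within):
            out.append(ConcordanceResult(
                ComparisonPair("A", float(i + 1), "A", float(i + 2), "within"),
                rho, spearman_t_pvalue(rho, 50), 50))
        return out

    def test_means_and_sd_arithmetic(self):
        s = concordance_summary(self._results([0.1, 0.2], [0.8, 0.9]))
        assert s["between"]["rho_mean"] == pytest.approx(0.15)
        assert s["within"]["rho_mean"] == pytest.approx(0.85)
        assert s["between"]["rho_sd"] == pytest.approx(np.std([0.1, 0.2], ddof=1))
        assert s["rho_sd_is"] == "standard deviation"

    def test_identical_rhos_give_contrast_p_one(self):
        s = concordance_summary(self._results([0.5, 0.5], [0.5, 0.5]))
        assert s["within_vs_between_p"] == pytest.approx(1.0)

    def test_one_kind_missing_gives_nan_contrast(self):
        s = concordance_summary(self._results([0.1, 0.2], []))
        assert math.isnan(s["within_vs_between_p"])

    def test_adjustment_spans_one_family(self):
        res = self._results([0.05, 0.1, 0.6], [0.7])
        adjust_results(res)
        qs = [r.q for r in res]
        ps = [r.p for r in res]
        np.testing.assert_allclose(qs, bh_adjust(ps), atol=1e-12)

    def test_invalid_pairs_excluded_from_family(self):
        res = self._results([0.5], [0.6])
        res.append(ConcordanceResult(
            ComparisonPair("A", 1.0, "C", 1.0, "between"), math.nan, math.nan, 1))
        adjust_results(res)
        assert math.isnan(res[-1].q)
        np.testing.assert_allclose([res[0].q, res[1].q],
                                   bh_adjust([res[0].p, res[1].p]))


class TestConcordanceAnalysis:
    def test_end_to_end_on_constructed_signatures(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=40)
        frames = []
        for study, tps in [("A", [1.0, 6.0]), ("B", [6.0])]:
            for t in tps:
                frames.append(sig_frame(study, t, base + rng.normal(0, 0.3, 40)))
                frames[-1]["timepoint_months"] = t
        sig = pd.concat(frames, ignore_index=True)
        results, tidy, summary = concordance_analysis(sig)
        assert len(tidy) == 3  # 2 between + 1 within
        assert set(tidy["kind"]) == {"between", "within"}
        assert (tidy["rho"] > 0.5).all()  # all derived from one shared base
        assert summary["n_significant_q05"] == 3


class TestClusterSignature:
    def test_identical_rows_merge_at_height_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = cluster_signature(m)
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_first_merge_is_closest_pair(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 3.0], [4.0, 0.0]],
                         index=["a", "b", "c"])
        res = cluster_signature(m)
        assert res.row_linkage[0, 2] == pytest.approx(3.0)

    def test_missing_entries_imputed_as_zero(self):
        m = pd.DataFrame([[np.nan, 0.0], [0.0, 0.0], [9.0, 9.0]],
                         index=["a", "b", "c"])
        res = cluster_signature(m)
        # with nan -> 0, rows a and b are identical and merge first at height 0
        assert res.row_linkage[0, 2] == pytest.approx(0.0)
        assert set(res.row_linkage[0, :2].astype(int)) == {0, 1}

    def test_single_column_keeps_column_order(self):
        m = pd.DataFrame([[1.0], [2.0]], columns=["only"])
        res = cluster_signature(m)
        assert res.col_order == ["only"]
        assert res.col_linkage is None

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 rows"):
            cluster_signature(pd.DataFrame([[1.0, 2.0]]))

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        a = cluster_signature(m)
        b = cluster_signature(m.copy())
        assert a.row_order == b.row_order
        np.testing.assert_array_equal(a.row_linkage, b.row_linkage)
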