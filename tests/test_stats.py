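"""Rank statistics against independent oracles (scipy, brute-force
permutation enumeration, hand rank arithmetic)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kruskal, mannwhitneyu

from bifurcbench.stats import (
    GroupSamples,
    analyze_groups,
    dunn_test,
    kruskal_wallis,
    median_iqr,
    null_rejection_rate,
)


class TestMedianIqr:
    def test_textbook_examples(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)
        assert median_iqr([7]) == (7.0, 7.0, 7.0)

    def test_median_matches_sort_oracle(self):
        vals = [0.17, 0.52, 0.65, 0.4, 0.6]
        med, q1, q3 = median_iqr(vals)
        assert med == sorted(vals)[2] == 0.52

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_quantiles_are_ordered_and_bracket_median(self, vals):
        med, q1, q3 = median_iqr(vals)
        assert q1 <= med <= q3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestKruskalWallis:
    def test_identical_groups_give_null_result(self):
        g = GroupSamples(list("abc"), [[2, 2], [2, 2], [2, 2]])
        r = kruskal_wallis(g)
        assert r.H == 0.0 and r.p == 1.0

    def test_h_matches_scipy_with_and_without_ties(self):
        cases = [
            ([1, 2], [3, 4], [5, 6]),
            ([1, 1, 2], [2, 3, 3], [4, 4, 5]),
            ([0.1, 0.9, 0.4], [0.2, 0.2], [1.5, 1.1, 0.7, 0.3]),
        ]
        for vals in cases:
            mine = kruskal_wallis(GroupSamples(list("abc"), list(vals)))
            ref = kruskal(*vals)
            assert mine.H == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_p_by_full_enumeration_oracle(self):
        # brute-force oracle: enumerate all 6! orderings of {1..6} into
        # groups of (2,2,2); distinct assignments collapse to 90 splits
        data = ([1, 2], [3, 4], [5, 6])
        r = kruskal_wallis(GroupSamples(list("abc"), list(data)))
        pooled = [1, 2, 3, 4, 5, 6]
        h_null = []
        for perm in itertools.permutations(pooled):
            g = (perm[:2], perm[2:4], perm[4:])
            h_null.append(kruskal(*g).statistic)
        oracle = np.mean(np.asarray(h_null) >= r.H - 1e-12)
        assert r.p_exact == pytest.approx(oracle, abs=1e-12)

    def test_two_groups_monotone_with_mann_whitney(self):
        # increasing group separation raises both |U - n1 n2 / 2| and H
        rng = np.random.default_rng(0)
        a = rng.normal(size=8)
        hs, us = [], []
        for shift in (0.0, 0.5, 1.5, 4.0):
            b = rng.normal(size=8) * 0 + a[::-1] + shift  # fixed shape, shifted
            r = kruskal_wallis(GroupSamples(["a", "b"], [a, b]), exact="never")
            u = mannwhitneyu(a, b).statistic
            hs.append(r.H)
            us.append(abs(u - 32.0))
        assert hs == sorted(hs)
        assert us == sorted(us)

    def test_chi_square_close_to_exact_for_small_groups(self):
        rng = np.random.default_rng(3)
        vals = [rng.normal(size=5), rng.normal(0.5, 1, 5), rng.normal(1.0, 1, 5)]
        r = kruskal_wallis(GroupSamples(list("abc"), vals), exact="always")
        assert abs(r.p - r.p_exact) < 0.05

    def test_label_permutation_invariance(self):
        vals = [[1.0, 5.0], [2.0, 7.0, 3.0], [8.0, 0.5]]
        base = kruskal_wallis(GroupSamples(list("abc"), vals)).H
        for perm in itertools.permutations(range(3)):
            h = kruskal_wallis(
                GroupSamples(list("abc"), [vals[i] for i in perm])
            ).H
            assert h == pytest.approx(base, rel=1e-12)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(GroupSamples(["a", "b"], [[1], [2]]))


class TestDunn:
    def test_gate_refuses_nonsignificant_omnibus(self):
        g = GroupSamples(list("abc"), [[1, 2], [1.5, 2.5], [2, 3]])
        with pytest.raises(ValueError, match="gated"):
            dunn_test(g, p_kw=0.3)

    def test_well_separated_groups_all_pairs_significant(self):
        g = GroupSamples(
            list("abc"),
            [list(range(1, 11)), list(range(20, 30)), list(range(100, 110))],
        )
        kw = kruskal_wallis(g)
        assert kw.p < 0.05
        d = dunn_test(g, kw.p)
        assert all(p < 0.05 for p in d.p.values())
        # hand rank arithmetic for the extreme pair: rank means 5.5 and 25.5,
        # pooled variance N(N+1)/12 = 77.5 -> z = -20 / sqrt(77.5 * 2/10)
        assert d.z[("a", "c")] == pytest.approx(-20.0 / np.sqrt(77.5 * 0.2), rel=1e-12)
        assert all(p < 0.05 for p in d.p_bonferroni.values())

    def test_duplicated_group_has_zero_z(self):
        g = GroupSamples(
            list("abc"),
            [[1, 2, 3, 4, 5], [1, 2, 3, 4, 5], [50, 51, 52, 53, 54]],
        )
        kw = kruskal_wallis(g)
        assert kw.p < 0.05
        d = dunn_test(g, kw.p)
        assert d.z[("a", "b")] == pytest.approx(0.0, abs=1e-12)
        assert d.p[("a", "b")] == pytest.approx(1.0)


class TestAnalyzeGroups:
    def test_dunn_present_only_when_significant(self):
        sep = GroupSamples(
            list("abc"),
            [[1, 2, 3, 4, 5], [10, 11, 12, 13, 14], [100, 101, 102, 103, 104]],
        )
        res = analyze_groups(sep, "metric")
        assert res.dunn is not None
        null = GroupSamples(list("abc"), [[1, 4, 2], [2, 3, 5], [1.5, 3.5, 4.5]])
        res2 = analyze_groups(null, "metric")
        assert res2.kw.p >= 0.05 and res2.dunn is None

    def test_summaries_are_median_iqr(self):
        g = GroupSamples(["x", "y"], [[1, 2, 3, 4, 5], [7.0]])
        res = analyze_groups(g)
        assert res.summaries["x"] == (3.0, 2.0, 4.0)
        assert res.summaries["y"] == (7.0, 7.0, 7.0)


class TestTypeIError:
    def test_null_rejection_rate_near_alpha(self):
        rate = null_rejection_rate(n_groups=3, n_per_group=5, reps=10_000,
                                   alpha=0.05, seed=0)
        assert 0.03 <= rate <= 0.07
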