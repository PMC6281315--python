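"""Exact nonparametric tests, verified against brute-force enumeration.

The brute-force oracles here are independent of the implementation: the
Wilcoxon null is enumerated over all 2^n sign assignments, the Mann-Whitney
null over all C(n+m, n) group assignments, with itertools.
"""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from gammakit.stats import (StatsError, mann_whitney_one_tailed,
                            normalize_timecourse, paired_comparison,
                            percent_change, wilcoxon_one_tailed)


def brute_wilcoxon_p(diffs, direction):
    """Enumerate all sign assignments of |d| ranks (no ties assumed)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    total = 0
    for signs in product([0, 1], repeat=len(ranks)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if direction == "less":
            count += w <= w_obs + 1e-9
        else:
            count += w >= w_obs - 1e-9
    return count / total


def brute_mannwhitney_p(x, y, direction):
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = ranks[: len(x)].sum()
    sums = [sum(c) for c in combinations(ranks, len(x))]
    if direction == "less":
        return np.mean([s <= rx + 1e-9 for s in sums])
    return np.mean([s >= rx - 1e-9 for s in sums])


class TestWilcoxonExact:
    @pytest.mark.parametrize("n,expected", [(5, 0.03125), (6, 0.015625),
                                            (8, 0.00390625)])
    def test_minimal_p_all_one_direction(self, n, expected):
        """All n pairs decreasing gives exactly 2^-n one-tailed."""
        before = np.arange(1.0, n + 1)
        after = before - np.linspace(0.5, 1.5, n)
        w, p = wilcoxon_one_tailed(before, after, direction="less")
        assert w == 0.0
        assert p == expected

    @given(st.lists(st.integers(-50, 50).filter(lambda v: v != 0),
                    min_size=5, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force(self, diffs):
        before = np.zeros(len(diffs))
        after = np.asarray(diffs, dtype=float)
        for direction in ("less", "greater"):
            _, p = wilcoxon_one_tailed(before, after, direction=direction)
            assert p == pytest.approx(brute_wilcoxon_p(diffs, direction), abs=1e-12)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(0)
        before = rng.normal(10, 2, 12)
        after = before + rng.normal(-1, 1, 12)
        _, p = wilcoxon_one_tailed(before, after, direction="less")
        ref = wilcoxon(after, before, alternative="less", mode="exact").pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_all_zero_differences_error(self):
        x = np.arange(6.0)
        with pytest.raises(StatsError, match="degenerate"):
            wilcoxon_one_tailed(x, x)

    def test_large_n_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(1)
        before = rng.normal(10, 2, 30)
        after = before + rng.normal(-0.8, 1, 30)
        _, p = wilcoxon_one_tailed(before, after, direction="less")
        ref = wilcoxon(after, before, alternative="less",
                       mode="approx", correction=True).pvalue
        assert p == pytest.approx(ref, rel=0.02)


class TestMannWhitneyExact:
    def test_complete_separation_3v3(self):
        u, p = mann_whitney_one_tailed([1, 2, 3], [4, 5, 6], direction="less")
        assert u == 0.0
        assert p == pytest.approx(1 / 20)

    def test_complete_separation_4v4(self):
        _, p = mann_whitney_one_tailed([1, 2, 3, 4], [5, 6, 7, 8], direction="less")
        assert p == pytest.approx(1 / 70)

    def test_identical_groups_no_evidence(self):
        _, p = mann_whitney_one_tailed([1.0, 2, 3, 4], [1.0, 2, 3, 4],
                                       direction="less")
        assert p >= 0.5

    @given(st.lists(st.integers(0, 20), min_size=3, max_size=6),
           st.lists(st.integers(0, 20), min_size=3, max_size=6))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_with_ties(self, x, y):
        for direction in ("less", "greater"):
            _, p = mann_whitney_one_tailed(x, y, direction=direction)
            assert p == pytest.approx(brute_mannwhitney_p(np.array(x, float),
                                                          np.array(y, float),
                                                          direction), abs=1e-12)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        u, p = mann_whitney_one_tailed(x, y, direction="less")
        ref = mannwhitneyu(x, y, alternative="less", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(StatsError):
            mann_whitney_one_tailed([], [1.0, 2, 3])


class TestNormalization:
    def test_constant_series_all_ones(self):
        out = normalize_timecourse(np.full(10, 3.7))
        np.testing.assert_allclose(out, 1.0)

    def test_worked_example(self):
        out = normalize_timecourse([2, 2, 2, 2, 2, 1, 1])
        np.testing.assert_allclose(out, [1, 1, 1, 1, 1, 0.5, 0.5])

    def test_zero_control_mean_errors(self):
        with pytest.raises(StatsError):
            normalize_timecourse([0, 0, 0, 0, 0, 1])

    @given(st.lists(st.floats(0.1, 100), min_size=6, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values):
        once = normalize_timecourse(values)
        twice = normalize_timecourse(once)
        np.testing.assert_allclose(once, twice, rtol=1e-12)


class TestPercentChange:
    def test_forty_percent_reduction(self):
        assert percent_change(10, 6) == pytest.approx(40.0)

    def test_no_change(self):
        assert percent_change(5, 5) == 0.0

    def test_paper_scale_values(self):
        assert percent_change(8.6e-10, 5.2e-10) == pytest.approx(39.5, abs=0.1)

    def test_nonpositive_before_errors(self):
        with pytest.raises(StatsError):
            percent_change(0, 1)

    def test_paired_comparison_reports_both_conventions(self):
        before = np.array([10.0, 8.0, 12.0, 9.0, 11.0])
        after = before * np.array([0.5, 0.6, 0.7, 0.55, 0.65])
        cmp = paired_comparison(before, after, direction="less")
        assert cmp.p_one_tailed == 0.03125
        assert cmp.significant
        per_rec = 100 * (1 - after / before)
        assert cmp.pct_change_mean == pytest.approx(per_rec.mean())
        pooled = 100 * (1 - after.mean() / before.mean())
        assert cmp.pct_change_pooled == pytest.approx(pooled)
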