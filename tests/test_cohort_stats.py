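"""Rank tests, FDR adjustment, bin comparisons, and group summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutindices import (
    bh_fdr,
    compare_by_bins,
    group_summary,
    kruskal_wallis,
    rank_sum_test,
)
from gutindices.exceptions import EmptyInputError, ValidationError


def pair_count_u(x, y):
    """U of x by direct pair counting (independent of any ranking code)."""
    return sum(
        1.0 if xi > yi else 0.5 if xi == yi else 0.0
        for xi in x
        for yi in y
    )


def permutation_p(x, y):
    """Two-sided permutation p: share of group labelings whose U deviates
    from n1*n2/2 by at least the observed deviation."""
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)
    mu = n1 * (n - n1) / 2
    obs = abs(pair_count_u(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n) if i not in set(idx)]
        total += 1
        if abs(pair_count_u(chosen, rest) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_fully_separated_groups(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 20)  # C(6,3)=20 labelings, 2 extreme

    def test_identical_multisets_give_p_one(self):
        r = rank_sum_test([1, 2, 2, 5], [1, 2, 2, 5], mode="exact")
        assert r.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyInputError):
            rank_sum_test([], [1.0])

    def test_auto_uses_exact_only_without_ties(self):
        tie_free = rank_sum_test([1, 2, 3], [4, 5, 6], mode="auto")
        tied = rank_sum_test([1, 2, 2], [2, 5, 6], mode="auto")
        assert tie_free.details["mode"] == "exact"
        assert tied.details["mode"] == "normal_approx"

    @pytest.mark.parametrize("n1", [2, 3, 4])
    def test_exact_matches_permutation_oracle_continuous(self, n1, rng):
        for _ in range(20):
            pooled = rng.normal(size=8)
            x, y = list(pooled[:n1]), list(pooled[n1:])
            r = rank_sum_test(x, y, mode="exact")
            assert r.p_value == pytest.approx(permutation_p(x, y), abs=1e-12)
            assert r.statistic == pytest.approx(pair_count_u(x, y), abs=1e-9)

    def test_exact_matches_permutation_oracle_with_ties(self, rng):
        for _ in range(20):
            pooled = rng.integers(0, 3, size=7)
            x, y = list(pooled[:3]), list(pooled[3:])
            r = rank_sum_test(x, y, mode="exact")
            assert r.p_value == pytest.approx(permutation_p(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact_at_moderate_n(self, rng):
        x, y = list(rng.normal(size=6)), list(rng.normal(1.0, size=6))
        exact = rank_sum_test(x, y, mode="exact").p_value
        approx = rank_sum_test(x, y, mode="normal_approx").p_value
        assert approx == pytest.approx(exact, abs=0.05)


class TestKruskalWallis:
    def test_worked_value(self):
        # rank sums 3, 7, 11 over N=6: H = 12/(6*7) * (9/2+49/2+121/2) - 21 = 32/7
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(32 / 7)
        assert r.details["df"] == 2

    def test_worked_value_against_direct_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        n = 6
        rank_sums = [3, 7, 11]
        h = 12 / (n * (n + 1)) * sum(r**2 / 2 for r in rank_sums) - 3 * (n + 1)
        assert kruskal_wallis(groups).statistic == pytest.approx(h)

    def test_total_tie_gives_zero_h_and_p_one(self):
        r = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])

    def test_invariant_under_monotone_transform(self, rng):
        groups = [list(rng.normal(size=8)), list(rng.normal(0.5, size=8)), list(rng.normal(1, size=8))]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([[math.exp(v) for v in g] for g in groups]).statistic
        assert h2 == pytest.approx(h1, abs=1e-9)

    def test_two_groups_agree_with_rank_sum_approximation(self, rng):
        x, y = list(rng.normal(size=10)), list(rng.normal(0.8, size=10))
        kw = kruskal_wallis([x, y]).p_value
        rs = rank_sum_test(x, y, mode="normal_approx").p_value
        # same midrank statistic; continuity correction accounts for the gap
        assert kw == pytest.approx(rs, abs=0.03)


class TestBhFdr:
    def test_hand_computed_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.05, 0.05, 0.05, 0.05]) == pytest.approx([0.05] * 4)
        assert bh_fdr([0.03]) == [0.03]

    def test_order_restored_to_input_order(self):
        adjusted = bh_fdr([0.04, 0.01])
        assert adjusted == pytest.approx([0.04, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, 1.5])

    def test_agrees_with_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=25)
        _, expected, _, _ = statsmodels.multipletests(p, method="fdr_bh")
        assert bh_fdr(list(p)) == pytest.approx(list(expected), abs=1e-12)

    @given(p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_monotone_dominating_and_capped(self, p):
        adjusted = bh_fdr(p)
        assert all(v - 1e-12 <= a <= 1.0 for a, v in zip(adjusted, p))
        # monotone in the order statistics of the input
        order = np.argsort(p)
        ranked = np.asarray(adjusted)[order]
        assert all(b >= a - 1e-12 for a, b in zip(ranked, ranked[1:]))


def _score_frame(rng, bins, n=12, shift=0.0):
    rows = []
    for i, label in enumerate(bins):
        for v in rng.normal(i * shift, 1.0, size=n):
            rows.append({"phenotype": label, "mapi": v})
    return pd.DataFrame(rows)


class TestCompareByBins:
    def test_omnibus_structure(self, rng):
        results = compare_by_bins(
            _score_frame(rng, ["healthy", "mild", "diseased"]), "phenotype", "omnibus"
        )
        assert len(results) == 1
        assert results[0].details["df"] == 2
        assert set(results[0].groups) == {"healthy", "mild", "diseased"}

    def test_pairwise_fdr_covers_all_pairs(self, rng):
        frame = _score_frame(rng, ["b1", "b2", "b3", "b4", "b5"])
        results = compare_by_bins(frame, "phenotype", "pairwise_fdr")
        assert len(results) == 10  # C(5,2)
        assert all(r.p_adjusted is not None for r in results)
        assert all(r.p_adjusted >= r.p_value - 1e-12 for r in results)

    def test_unknown_bin_and_small_bins_excluded(self, rng):
        frame = _score_frame(rng, ["healthy", "mild"])
        frame = pd.concat(
            [frame, pd.DataFrame([{"phenotype": "unknown", "mapi": 0.0},
                                  {"phenotype": "singleton", "mapi": 1.0}])],
            ignore_index=True,
        )
        results = compare_by_bins(frame, "phenotype", "omnibus")
        assert set(results[0].groups) == {"healthy", "mild"}

    def test_insufficient_bins_error_lists_usable(self, rng):
        frame = _score_frame(rng, ["only"])
        with pytest.raises(ValidationError, match="only"):
            compare_by_bins(frame, "phenotype", "omnibus")

    def test_shifted_groups_detected(self, rng):
        frame = _score_frame(rng, ["healthy", "diseased"], n=200, shift=1.0)
        results = compare_by_bins(frame, "phenotype", "omnibus")
        assert results[0].p_value < 0.05


class TestGroupSummary:
    def test_two_point_bin(self):
        frame = pd.DataFrame({"phenotype": ["h", "h"], "mapi": [-5.0, -6.0]})
        (s,) = group_summary(frame, "phenotype")
        assert s.mean == pytest.approx(-5.5)
        assert s.sd == pytest.approx(1.0 / math.sqrt(2))  # |diff|/sqrt(2)
        assert s.median == pytest.approx(-5.5)

    def test_single_member_bin_has_no_sd(self):
        frame = pd.DataFrame({"phenotype": ["h"], "mapi": [-5.0]})
        (s,) = group_summary(frame, "phenotype")
        assert s.n == 1 and s.sd is None

    def test_missing_scores_excluded_and_counted(self):
        frame = pd.DataFrame(
            {"phenotype": ["h", "h", "h"], "mapi": [-5.0, np.nan, -6.0]}
        )
        (s,) = group_summary(frame, "phenotype")
        assert s.n == 2 and s.n_excluded == 1
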