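import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sigcontext.stats import (
    PairedExposures,
    bh_fdr,
    boxplot_summary,
    compare_contexts,
    exposure_sv_correlation,
    fisher_combine,
    pca_project,
    rank_sum_test,
    signed_rank_effect,
    spearman_trend,
    tertile_grouping,
)


def pairs_of(diffs):
    d = np.asarray(diffs, dtype=float)
    return PairedExposures([f"s{i}" for i in range(len(d))], d, np.zeros(len(d)))


def brute_force_effect(diffs):
    """Independent implementation: explicit ranking of |d| with average ties."""
    d = np.array([x for x in diffs if x != 0], dtype=float)
    order = np.abs(d)
    ranks = np.empty(len(d))
    for i, v in enumerate(order):
        less = (order < v).sum()
        equal = (order == v).sum()
        ranks[i] = less + (equal + 1) / 2
    W = float((np.sign(d) * ranks).sum())
    R = float(ranks.sum())
    return W, R, W / R


class TestSignedRankEffect:
    def test_all_positive_differences_give_plus_one(self):
        res = signed_rank_effect(pairs_of([0.1, 0.5, 0.3]))
        assert res.effect == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # d = (+1, +2, -3): ranks (1, 2, 3), W = 1 + 2 - 3 = 0
        res = signed_rank_effect(pairs_of([1, 2, -3]))
        assert res.W == 0 and res.R == 6 and res.effect == 0.0

    def test_negation_antisymmetry(self):
        d = [0.4, -0.2, 0.9, 0.1]
        a = signed_rank_effect(pairs_of(d))
        b = signed_rank_effect(pairs_of([-x for x in d]))
        assert a.effect == pytest.approx(-b.effect)

    def test_zero_differences_dropped(self):
        res = signed_rank_effect(pairs_of([0.0, 1.0, 0.0, 2.0]))
        assert res.n == 2 and res.effect == 1.0

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            signed_rank_effect(pairs_of([0.0, 0.0]))

    @given(
        diffs=st.lists(
            st.integers(-5, 5).filter(lambda x: x != 0), min_size=1, max_size=8
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_for_small_n(self, diffs):
        res = signed_rank_effect(pairs_of(diffs))
        W, R, eff = brute_force_effect(diffs)
        assert res.W == pytest.approx(W)
        assert res.R == pytest.approx(R)
        assert res.effect == pytest.approx(eff)
        assert -1 <= res.effect <= 1


class TestRankSum:
    def test_identical_groups_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_separated_triples_exact_p(self):
        # all 3 of group b above group a: 2 x (1 / C(6,3)) = 0.1 two-sided
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_and_asymptotic_agree_at_moderate_n(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.3, 1, 30)
        p_asym = rank_sum_test(a, b)
        p_exact = float(sps.mannwhitneyu(a, b, method="exact").pvalue)
        assert abs(p_asym - p_exact) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestFisherCombine:
    def test_single_p_is_identity(self):
        for p in (0.01, 0.3, 0.77):
            assert fisher_combine([p]) == pytest.approx(p, abs=1e-12)

    def test_all_ones_give_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form_half_half(self):
        # X = -4 ln 0.5, combined p = exp(-X/2) (1 + X/2)
        X = -4 * np.log(0.5)
        expected = np.exp(-X / 2) * (1 + X / 2)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(expected, abs=1e-10)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    @given(
        ps=st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=10)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_chi2_oracle(self, ps):
        X = -2 * sum(np.log(p) for p in ps)
        oracle = 1.0 - sps.chi2.cdf(X, 2 * len(ps))
        assert fisher_combine(ps) == pytest.approx(oracle, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_step_up_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.04, 0.04, 0.04]).tolist() == pytest.approx([0.04] * 3)

    def test_adjusted_at_least_raw_and_order_invariant(self, rng):
        p = rng.random(20)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        perm = rng.permutation(20)
        assert np.allclose(bh_fdr(p[perm]), adj[perm])


class TestSpearmanTrend:
    def test_monotone_increase_gives_one(self):
        levels = np.repeat([1, 2, 3, 4, 5], 4)
        weights = levels * 0.1  # strictly increasing with level, tied within
        rho, p = spearman_trend(levels, weights)
        assert rho == pytest.approx(1.0)

    def test_reversed_levels_negate_rho(self):
        rng = np.random.default_rng(0)
        levels = np.repeat([1, 2, 3], 10)
        weights = levels + rng.normal(0, 0.5, 30)
        r1, _ = spearman_trend(levels, weights)
        r2, _ = spearman_trend(levels.max() + 1 - levels, weights)
        assert r1 == pytest.approx(-r2)

    def test_null_data_rho_near_zero(self, rng):
        levels = np.tile([1, 2, 3, 4, 5], 40)
        weights = rng.random(200)
        rho, _ = spearman_trend(levels, weights)
        assert abs(rho) < 3 / np.sqrt(200)

    def test_constant_weights_undefined(self):
        rho, p = spearman_trend([1, 2, 3], [0.5, 0.5, 0.5])
        assert np.isnan(rho)


class TestPCA:
    def test_identical_rows_project_to_origin(self):
        X = np.tile(np.arange(5.0), (4, 1))
        coords, ev, total = pca_project(X)
        assert np.allclose(coords, 0.0, atol=1e-10)

    def test_two_rows_symmetric_on_pc1(self):
        X = np.array([[1.0, 0.0, 2.0], [3.0, 4.0, 0.0]])
        coords, ev, total = pca_project(X)
        assert coords[0, 0] == pytest.approx(-coords[1, 0])
        assert np.allclose(coords[:, 1], 0.0, atol=1e-10)

    def test_explained_variance_sums_to_total(self, rng):
        X = rng.normal(size=(10, 6))
        coords, ev, total = pca_project(X, n_components=6)
        col_var = X.var(axis=0, ddof=1).sum()
        assert total == pytest.approx(col_var)


class TestTertiles:
    def test_nine_distinct_values_split_evenly(self):
        labels = tertile_grouping(np.arange(9.0))
        assert sorted(labels) == ["high"] * 3 + ["low"] * 3 + ["middle"] * 3

    def test_all_equal_collapse_to_low(self):
        labels = tertile_grouping(np.full(6, 2.0))
        assert (labels == "low").all()

    def test_invariant_under_monotone_transform(self, rng):
        v = rng.random(30)
        assert (tertile_grouping(v) == tertile_grouping(np.exp(5 * v))).all()


class TestSVCorrelation:
    def test_monotone_link_gives_one(self):
        w = np.linspace(0.1, 0.9, 20)
        rho, _ = exposure_sv_correlation(w, np.exp(3 * w))
        assert rho == pytest.approx(1.0)

    def test_independent_pairs_rho_small(self, rng):
        rho, _ = exposure_sv_correlation(rng.random(100), rng.random(100))
        assert abs(rho) < 0.3

    def test_constant_counts_undefined(self):
        rho, _ = exposure_sv_correlation([0.1, 0.2, 0.3], [5, 5, 5])
        assert np.isnan(rho)


class TestBoxplotSummary:
    def test_whiskers_clip_to_fence(self):
        v = np.concatenate([np.arange(1, 12.0), [100.0]])  # one far outlier
        s = boxplot_summary(v)
        q1, q3 = np.percentile(v, [25, 75])
        assert s["upper_whisker"] <= q3 + 1.5 * (q3 - q1)
        assert s["upper_whisker"] == 11.0
        assert s["lower_whisker"] == 1.0


class TestCompareContexts:
    def test_paired_comparison_table(self):
        import pandas as pd

        rows = []
        rng = np.random.default_rng(5)
        for i in range(12):
            late = 0.4 + rng.normal(0, 0.02)
            early = 0.1 + rng.normal(0, 0.02)
            rows += [(f"s{i}", "late", "SBS8", late), (f"s{i}", "early", "SBS8", early)]
        table = pd.DataFrame(rows, columns=["sample", "context", "signature", "weight"])
        res = compare_contexts(table, "SBS8", "late", "early")
        assert res["effect_size"] == pytest.approx(1.0)
        assert res["p"] < 0.01
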