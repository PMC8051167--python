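import itertools
import logging
import math

import numpy as np
import pytest

from consreg.classify import PatternClass
from consreg.stats import (
    chisq_class_distribution,
    chisq_goodness_of_fit,
    mannwhitney_conservation,
    stars,
    wilcoxon_paired_counts,
)


def exact_mwu_pvalue(x, y):
    """Two-sided exact Mann-Whitney p by full permutation enumeration (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(sample1, rest):
        return sum(a > b for a in sample1 for b in rest)

    u_obs = u_of(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        s1 = [pooled[i] for i in comb]
        s2 = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(u_of(s1, s2))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def exact_wilcoxon_pvalue(diffs):
    """Two-sided exact signed-rank p by full sign-flip enumeration (no ties)."""
    d = np.array([v for v in diffs if v != 0], dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= w_obs:
            count += 1
    return count / 2 ** n


class TestStars:
    @pytest.mark.parametrize(
        "p, mark",
        [(0.5, "ns"), (0.05, "ns"), (0.049, "*"), (0.009, "**"),
         (0.0009, "***"), (0.00009, "****"), (0.0, "****"), (1.0, "ns")],
    )
    def test_cutpoints(self, p, mark):
        assert stars(p) == mark

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stars(1.5)


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        res = mannwhitney_conservation({1: [0.2, 0.3, 0.4], 2: [0.2, 0.3, 0.4]})
        assert res[(1, 2)].p_value == pytest.approx(1.0)
        assert res[(1, 2)].stars == "ns"

    def test_constant_identical_groups_degenerate_case(self):
        res = mannwhitney_conservation({1: [0.5, 0.5], 2: [0.5, 0.5]})
        assert res[(1, 2)].p_value == 1.0

    def test_complete_separation_small_n(self):
        res = mannwhitney_conservation({1: [1, 2, 3], 2: [10, 11, 12]})
        r = res[(1, 2)]
        # U = 0 for the low group; exact two-sided p = 2/20
        assert min(r.statistic, 9 - r.statistic) == 0
        assert r.p_value == pytest.approx(0.1)
        assert r.p_value == pytest.approx(exact_mwu_pvalue([1, 2, 3], [10, 11, 12]))

    def test_matches_permutation_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            n1, n2 = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            vals = rng.choice(np.arange(100), size=n1 + n2, replace=False)
            x, y = list(vals[:n1]), list(vals[n1:])
            res = mannwhitney_conservation({"a": x, "b": y})
            assert res[("a", "b")].p_value == pytest.approx(exact_mwu_pvalue(x, y), abs=1e-12)

    def test_symmetric_matrix_and_empty_group_rejected(self):
        res = mannwhitney_conservation({1: [1, 2], 2: [3, 4], 3: [5, 6]})
        assert res[(1, 2)] is res[(2, 1)]
        assert len(res) == 6
        with pytest.raises(ValueError, match="empty"):
            mannwhitney_conservation({1: [1.0], 2: []})


class TestChiSquare:
    def test_pooled_proportions_give_zero_statistic(self):
        observed = {
            1: {PatternClass.TFBS: 50, PatternClass.TFBS_SS: 30,
                PatternClass.SS: 10, PatternClass.NOT_IDENTIFIED: 10},
            2: {PatternClass.TFBS: 25, PatternClass.TFBS_SS: 15,
                PatternClass.SS: 5, PatternClass.NOT_IDENTIFIED: 5},
        }
        res = chisq_class_distribution(observed)
        for r in res.values():
            assert r.statistic == pytest.approx(0.0, abs=1e-12)
            assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_four_cell_example(self):
        obs = [40, 30, 20, 10]
        props = [0.25, 0.25, 0.25, 0.25]
        r = chisq_goodness_of_fit(obs, props)
        expected = 25.0
        chi2 = sum((o - expected) ** 2 / expected for o in obs)
        assert r.statistic == pytest.approx(chi2, abs=1e-9)
        from scipy.stats import chi2 as chi2_dist

        assert r.p_value == pytest.approx(float(chi2_dist.sf(chi2, 3)), abs=1e-12)

    def test_small_expected_collapses_ss_into_tfbs_ss(self, caplog):
        observed = {
            1: {PatternClass.TFBS: 8, PatternClass.TFBS_SS: 1,
                PatternClass.SS: 1, PatternClass.NOT_IDENTIFIED: 2},
            2: {PatternClass.TFBS: 5, PatternClass.TFBS_SS: 1,
                PatternClass.SS: 0, PatternClass.NOT_IDENTIFIED: 1},
        }
        with caplog.at_level(logging.WARNING):
            res = chisq_class_distribution(observed)
        assert "collapsing SS" in caplog.text
        assert all(len(r.n_per_group) == 1 for r in res.values())

    def test_type_one_error_near_alpha(self):
        # multinomial draws at the expected proportions reject ~5% at alpha=0.05
        rng = np.random.default_rng(17)
        props = np.array([0.5, 0.2, 0.2, 0.1])
        reps, n = 2000, 200
        rejections = 0
        for counts in rng.multinomial(n, props, size=reps):
            if chisq_goodness_of_fit(counts, props).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_class_distribution({1: {PatternClass.TFBS: 0}})


class TestWilcoxon:
    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_paired_counts([1, 2, 3], [1, 2, 3])

    def test_uniform_sign_gives_extreme_statistic(self):
        a = [10, 12, 14, 16, 18, 20]
        b = [1, 2, 3, 4, 5, 6]
        r = wilcoxon_paired_counts(a, b)
        assert r.statistic == pytest.approx(0.0)  # all mass on one side
        assert r.p_value == pytest.approx(2 / 2 ** 6)

    def test_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(6):
            n = int(rng.integers(5, 9))
            a = rng.choice(np.arange(1, 60), size=n, replace=False).astype(float)
            b = a + rng.choice([-1, 1], size=n) * rng.choice(np.arange(1, 50), size=n, replace=False) / 100.0
            r = wilcoxon_paired_counts(list(a), list(b))
            assert r.p_value == pytest.approx(exact_wilcoxon_pvalue(a - b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            wilcoxon_paired_counts([1, 2], [1])
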