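"""Statistical harness: exact small-sample behavior and calibration."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

from somnet.stats import TestResult as StatResult
from somnet.stats import (chi_squared_2x2, group_comparison_suite,
                          kruskal_wallis_dunn, ks_normality, mann_whitney_u,
                          paired_t, results_frame, stars)


def exact_mwu_p(x, y):
    """Enumeration oracle: two-sided p over all group assignments."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_stat(range(n))
    center = n * (N - n) / 2.0
    dev = abs(u_obs - center)
    us = [u_stat(c) for c in combinations(range(N), n)]
    return np.mean([abs(u - center) >= dev - 1e-12 for u in us])


def kw_h_oracle(groups):
    """Rank-formula H with tie correction, written independently."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    rank_of = np.empty(len(pooled))
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        rank_of[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    N = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = rank_of[start:start + len(g)]
        h += len(g) * (r.mean() - (N + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (N ** 3 - N)
    return h / tie


class TestMannWhitney:
    def test_separated_triples_exact_p_is_one_tenth(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic in (0.0, 9.0)
        assert np.isclose(r.p, 0.1)

    def test_identical_samples_give_central_u(self):
        r = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isclose(r.statistic, 8.0)  # n*m/2
        assert r.p > 0.85

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle_on_small_samples(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=5)
        y = r.normal(size=4) + 0.5
        assert np.isclose(mann_whitney_u(x, y).p, exact_mwu_p(x, y), atol=1e-12)

    def test_normal_approximation_close_to_exact_at_n20(self, rng):
        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(size=20) + rng.uniform(-0.5, 0.5)
            from scipy.stats import mannwhitneyu
            exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            approx = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(exact - approx) <= 0.01

    def test_order_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=15)
        assert mann_whitney_u(x, y).p == mann_whitney_u(x[::-1], y[::-1]).p


class TestPairedT:
    def test_alternating_differences_give_t_zero(self):
        r = paired_t([1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert np.isclose(r.statistic, 0.0) and np.isclose(r.p, 1.0)

    def test_closed_form_on_difference_triple(self):
        r = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert np.isclose(r.statistic, 2.0 * np.sqrt(3.0))
        assert np.isclose(r.statistic, 3.4641, atol=1e-4)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_t([1.0, 2.0], [1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestKruskalWallisDunn:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = kruskal_wallis_dunn([g, g, g])
        assert len(res) == 1  # no post hoc
        assert res[0].statistic < 1e-9 and res[0].p > 0.99

    def test_h_matches_rank_formula_oracle(self, rng):
        for _ in range(10):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(3)]
            res = kruskal_wallis_dunn(groups, alpha=1.1)
            assert np.isclose(res[0].statistic, kw_h_oracle(groups), atol=1e-10)

    def test_tiny_separated_groups_vs_rank_permutation(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                  np.array([5.0, 6.0])]
        res = kruskal_wallis_dunn(groups, alpha=0.2)
        h_obs = res[0].statistic
        assert np.isclose(h_obs, kw_h_oracle(groups), atol=1e-12)
        # exhaustive permutation of the 6 ranks over the group layout
        hs = []
        for perm in permutations(range(1, 7)):
            arr = np.array(perm, dtype=float)
            hs.append(kw_h_oracle([arr[:2], arr[2:4], arr[4:]]))
        p_perm = np.mean([h >= h_obs - 1e-12 for h in hs])
        assert np.isclose(p_perm, 6 / 90)
        assert abs(res[0].p - p_perm) < 0.05  # chi2 approximation accuracy

    def test_dunn_bonferroni_never_decreases_and_caps(self):
        r = np.random.default_rng(1)
        groups = [r.normal(size=10), r.normal(size=10) + 3, r.normal(size=10) + 6,
                  r.normal(size=10)]
        res = kruskal_wallis_dunn(groups)
        posthoc = [t for t in res if t.test == "dunn"]
        assert len(posthoc) == 6
        for t in posthoc:
            assert t.p_corrected >= t.p - 1e-15
            assert t.p_corrected <= 1.0
            assert np.isclose(t.p_corrected, min(1.0, t.p * 6))

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1.0, 2.0], [3.0, 4.0]])


class TestChiSquared:
    def test_balanced_table_chi2_zero(self):
        r = chi_squared_2x2([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and np.isclose(r.p, 1.0)

    def test_perfect_association_uncorrected(self):
        r = chi_squared_2x2([[20, 0], [0, 20]], correction=False)
        assert np.isclose(r.statistic, 40.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared_2x2([[0, 0], [5, 5]])


class TestKsNormality:
    def test_normal_scores_pass(self, rng):
        from scipy.stats import norm
        x = norm.ppf((np.arange(100) + 0.5) / 100)
        assert ks_normality(x).p > 0.5

    def test_uniform_sample_rejected_with_power(self, rng):
        x = rng.uniform(0, 1, size=500)
        assert ks_normality(x).p < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestSuiteAndResults:
    @staticmethod
    def null_metrics(rng, n_per_cell=12, bands=("delta", "theta"),
                     stages=("W", "N2", "N3"), shift=0.0):
        rows = []
        for band in bands:
            for stage in stages:
                for group, delta in (("control", 0.0), ("patient", shift)):
                    for k in range(n_per_cell):
                        l = rng.normal()
                        rows.append({
                            "subject": f"{group[0]}{k % 4}", "group": group,
                            "band": band, "stage": stage,
                            "ge": rng.normal() + delta,
                            "left_strength": l,
                            "right_strength": l + rng.normal()})
        return pd.DataFrame(rows)

    def test_suite_covers_every_cell_and_flags_shift(self, rng):
        df = self.null_metrics(rng, n_per_cell=40, shift=1.5)
        res = group_comparison_suite(df)
        mwu = [t for t in res if t.test == "mann-whitney-u" and t.metric == "ge"]
        assert len(mwu) == 6
        assert all(t.p < 0.05 for t in mwu)
        kw = [t for t in res if t.test == "kruskal-wallis"]
        assert len(kw) == 4  # 2 bands x 2 groups
        pt = [t for t in res if t.test == "paired-t"]
        assert len(pt) == 12  # band x stage x group

    def test_subject_unit_collapses_epochs(self, rng):
        df = self.null_metrics(rng, n_per_cell=12)
        res = group_comparison_suite(df, unit="subject")
        mwu = [t for t in res if t.test == "mann-whitney-u"][0]
        assert mwu.n == (4, 4)

    def test_missing_required_column_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            group_comparison_suite(pd.DataFrame({"subject": [], "group": []}))

    def test_results_frame_has_stars_and_caps(self, rng):
        df = self.null_metrics(rng, n_per_cell=30, shift=2.0)
        frame = results_frame(group_comparison_suite(df))
        assert (frame["p_corrected"] >= frame["p_raw"] - 1e-12).all()
        sig = frame[(frame["test"] == "mann-whitney-u") & (frame["metric"] == "ge")]
        assert set(sig["stars"]) <= {"", "*", "**", "***"}
        assert (sig["stars"] != "").all()

    def test_star_thresholds(self):
        assert stars(0.04) == "*" and stars(0.004) == "**"
        assert stars(0.0009) == "***" and stars(0.2) == ""

    def test_corrected_p_below_raw_rejected(self):
        with pytest.raises(ValueError):
            StatResult(test="t", statistic=0.0, p=0.5, n=(3,), p_corrected=0.1)
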