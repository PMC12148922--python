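"""Rank tests against enumeration oracles, ICC parameter recovery and
cross-checks, Spearman banding, and a-priori power searches."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from swemuscle.stats import (
    PowerSpec,
    anova_power,
    anova_power_n,
    group_comparison,
    icc_3_3,
    kruskal_wallis,
    pairwise_wilcoxon,
    rank_sum_w,
    spearman,
    spearman_band,
    wmw_power,
    wmw_power_n,
)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        """Three fully separated groups of 3: rank sums 6, 15, 24 give
        H = 12/(9*10) * (12+75+192) - 3*10 ... = 7.2, no ties."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(1 - sps.chi2.cdf(7.2, 2))

    def test_identical_groups(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_p_matches_monte_carlo_oracle(self, rng):
        """Exhaustive-permutation p agrees with an independent Monte-Carlo
        permutation oracle within sampling error."""
        groups = [[1.2, 3.4, 0.5], [2.2, 4.1], [5.0, 0.1, 2.9]]
        res = kruskal_wallis(groups, method="exact")
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        h_obs = kruskal_wallis(groups).statistic
        hits = 0
        n_mc = 20000
        for _ in range(n_mc):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            h = sps.kruskal(*parts).statistic
            hits += h >= h_obs - 1e-9
        assert res.p_value == pytest.approx(hits / n_mc, abs=0.02)

    def test_exact_two_tiny_groups(self):
        """Total n = 6: the exact permutation p of fully separated groups is
        2/20 = 0.1 (forward and reversed order)."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]], method="exact")
        assert res.p_value == pytest.approx(0.1)

    def test_ties_match_scipy(self, rng):
        groups = [rng.integers(0, 4, 8).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups)
        h, p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)


class TestPairwiseWilcoxon:
    def test_rank_sum_of_first_group(self):
        w, z, p = rank_sum_w([1, 2, 3], [4, 5, 6])
        assert w == 6.0

    def test_identical_groups_z_zero(self):
        w, z, p = rank_sum_w([5.0, 5.0], [5.0, 5.0])
        assert z == 0.0 and p == 1.0

    def test_swap_symmetry(self):
        _, z1, p1 = rank_sum_w([1, 2, 3], [2, 4, 6])
        _, z2, p2 = rank_sum_w([2, 4, 6], [1, 2, 3])
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_asymptotic_p_matches_scipy_tie_corrected(self, rng):
        x = rng.integers(0, 5, 12).astype(float)
        y = rng.integers(1, 6, 10).astype(float)
        _, _, p = rank_sum_w(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=False).pvalue
        assert p == pytest.approx(ref)

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact p equals a brute-force enumeration over all assignments of
        the pooled (tie-free) values to the two groups."""
        x = list(rng.uniform(0, 1, 4))
        y = list(rng.uniform(0, 1, 5))
        res = pairwise_wilcoxon([x, y], method="exact")[0]
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        n1 = len(x)
        mean = n1 * (len(pooled) + 1) / 2
        w_obs = ranks[:n1].sum()
        dev = abs(w_obs - mean)
        hits = total = 0
        for idx in combinations(range(len(pooled)), n1):
            w = ranks[list(idx)].sum()
            total += 1
            hits += abs(w - mean) >= dev - 1e-9
        assert res.p_value == pytest.approx(hits / total)

    def test_all_pairs_reported(self):
        pairs = pairwise_wilcoxon([[1, 2], [3, 4], [5, 6]], labels=["a", "b", "c"])
        assert [p.groups for p in pairs] == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_holm_adjustment_monotone(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        pairs = pairwise_wilcoxon(groups, adjust="holm")
        assert all(p.p_adjusted >= p.p_value for p in pairs)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon([[1.0], []])


def test_group_comparison_gates_pairwise(rng):
    sep = [list(rng.normal(i * 3, 0.5, 8)) for i in range(3)]
    res = group_comparison(sep)
    assert res.significant and res.pairs is not None and len(res.pairs) == 3
    null = [[1.0, 2.0], [1.5, 2.5], [1.2, 2.2]]
    res2 = group_comparison(null)
    assert not res2.significant and res2.pairs is None


class TestSpearman:
    def test_monotone_data(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == 1.0 and res.band == "good_to_excellent"

    def test_band_cuts(self):
        assert spearman_band(0.487) == "fair"
        assert spearman_band(0.76) == "good_to_excellent"
        assert spearman_band(0.75) == "moderate_to_good"
        assert spearman_band(0.50) == "moderate_to_good"
        assert spearman_band(0.25) == "fair"
        assert spearman_band(-0.6) == "moderate_to_good"
        assert spearman_band(0.24) == "below_fair"

    def test_tied_data_matches_rank_oracle(self, rng):
        """Average-rank rho on tied data equals the Pearson correlation of
        hand-assigned average ranks (independent oracle, n <= 8)."""
        for _ in range(10):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 4, 8).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue

            def avg_ranks(v):
                order = sorted(range(len(v)), key=lambda i: v[i])
                ranks = [0.0] * len(v)
                i = 0
                while i < len(v):
                    j = i
                    while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                        j += 1
                    r = (i + j) / 2 + 1
                    for t in range(i, j + 1):
                        ranks[order[t]] = r
                    i = j + 1
                return ranks

            rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
            mx, my = np.mean(rx), np.mean(ry)
            num = np.sum((np.array(rx) - mx) * (np.array(ry) - my))
            den = math.sqrt(
                np.sum((np.array(rx) - mx) ** 2) * np.sum((np.array(ry) - my) ** 2)
            )
            if den == 0:
                continue
            assert spearman(x, y).rho == pytest.approx(num / den, rel=1e-12)

    def test_missing_pairs_dropped(self):
        res = spearman([1, 2, np.nan, 4], [2, 4, 6, 8])
        assert res.n == 3

    def test_zero_variance_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert not res.defined and res.band is None

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestICC:
    def test_perfect_agreement(self):
        x = np.repeat(np.arange(10.0)[:, None], 3, axis=1)
        res = icc_3_3(x)
        assert res.icc == pytest.approx(1.0)
        assert res.sem == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_against_closed_form(self):
        """n=200 subjects, subject SD 1.0, error SD 0.5: the average-of-3 ICC
        converges to 1 / (1 + 0.25/3)."""
        rng = np.random.default_rng(42)
        n, k = 200, 3
        x = rng.normal(0, 1.0, (n, 1)) + rng.normal(0, 0.5, (n, k))
        res = icc_3_3(x)
        expected = 1.0 / (1.0 + 0.25 / 3)
        assert res.icc == pytest.approx(expected, abs=0.05)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_pure_noise_icc_near_zero(self):
        """With zero subject variance the estimator centres on 0: the mean
        over independent n=200 simulations lies within ±0.1 (one draw has
        sampling SD ≈ 0.2 on the average-measures scale)."""
        rng = np.random.default_rng(7)
        vals = [icc_3_3(rng.normal(0, 1.0, (200, 3))).icc for _ in range(40)]
        assert abs(np.mean(vals)) <= 0.1

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n, k = 25, 3
        x = rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.6, (n, k)) + np.array([[0.0, 0.3, -0.2]])
        mine = icc_3_3(x)
        long = pd.DataFrame(
            {
                "t": np.repeat(np.arange(n), k),
                "r": np.tile(np.arange(k), n),
                "v": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="t", raters="r", ratings="v")
        row = ref[ref.Type == "ICC(A,k)"].iloc[0]
        assert mine.icc == pytest.approx(row.ICC, rel=1e-9)
        assert mine.ci95[0] == pytest.approx(row.CI95[0], abs=0.011)
        assert mine.ci95[1] == pytest.approx(row.CI95[1], abs=0.011)
        row_c = ref[ref.Type == "ICC(C,k)"].iloc[0]
        mine_c = icc_3_3(x, variant="consistency")
        assert mine_c.icc == pytest.approx(row_c.ICC, rel=1e-9)

    def test_ci_coverage_near_nominal(self):
        """95% CI covers the true variance-component ICC in [0.92, 0.98] of
        500 simulated studies."""
        rng = np.random.default_rng(2024)
        n, k = 30, 3
        true_icc = 1.0 / (1.0 + 0.25 / 3)
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            x = rng.normal(0, 1.0, (n, 1)) + rng.normal(0, 0.5, (n, k))
            lo, hi = icc_3_3(x).ci95
            covered += lo <= true_icc <= hi
        assert 0.92 <= covered / n_sim <= 0.98

    def test_listwise_deletion(self):
        x = np.repeat(np.arange(10.0)[:, None], 3, axis=1)
        x[0, 1] = np.nan
        assert icc_3_3(x).n == 9

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc_3_3(np.ones((1, 3)))

    def test_sem_is_pooled_sd_times_sqrt_one_minus_icc(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (20, 1)) + rng.normal(0, 0.5, (20, 3))
        res = icc_3_3(x)
        pooled = math.sqrt(np.mean(np.var(x, axis=0, ddof=1)))
        assert res.sem == pytest.approx(pooled * math.sqrt(1 - res.icc))


class TestPower:
    def test_anova_sample_size(self):
        assert anova_power_n(PowerSpec()) == 45

    def test_anova_threshold_is_sharp(self):
        spec = PowerSpec()
        n = anova_power_n(spec)
        assert anova_power(n, spec) >= spec.power
        assert anova_power(n - 1, spec) < spec.power

    def test_anova_monotone_in_effect_size(self):
        assert anova_power_n(PowerSpec(effect_f=0.96)) < anova_power_n(PowerSpec())

    def test_anova_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.power")
        ref = sm.FTestAnovaPower().solve_power(
            effect_size=0.48, alpha=0.05, power=0.80, k_groups=3
        )
        assert anova_power_n(PowerSpec()) == math.ceil(ref)

    def test_wmw_sample_size(self):
        assert wmw_power_n(PowerSpec()) == 38

    def test_wmw_threshold_is_sharp(self):
        spec = PowerSpec()
        n = wmw_power_n(spec)
        assert wmw_power(n, spec) >= spec.power
        assert wmw_power(n - 2, spec) < spec.power

    def test_wmw_are_one_reduces_to_t_test(self):
        """With ARE forced to 1 the search degenerates to the even-allocation
        noncentral-t two-sample size, cross-checked against statsmodels."""
        sm = pytest.importorskip("statsmodels.stats.power")
        n = wmw_power_n(PowerSpec(are_correction=1.0))
        ref = sm.TTestIndPower().solve_power(
            effect_size=0.96, alpha=0.05, power=0.80, ratio=1.0
        )
        assert n == 2 * math.ceil(ref)

    def test_wmw_halved_effect_roughly_quadruples_n(self):
        n1 = wmw_power_n(PowerSpec(effect_f=0.48))
        n2 = wmw_power_n(PowerSpec(effect_f=0.24))
        assert 3.3 <= n2 / n1 <= 4.7

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_f=0.0)
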