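"""Statistical layer: exact rank-sum, OLS, ANCOVA, correlations, summaries."""

import itertools
import math

import numpy as np
import pytest

from erythrotomo.containers import CellRecord, SubjectRecord
from erythrotomo.cohort_stats import (
    ancova_slopes,
    correlations,
    linear_fit_ci,
    load_fluctuation_table,
    pooled_t_test,
    summarize_cohort,
    wilcoxon_rank_sum,
)


def ranksum_enumeration(a, b):
    """Brute-force null distribution of the rank-sum statistic.

    Returns (two-sided p for the observed split, dict U -> count) by
    enumerating all C(n+m, n) assignments of the pooled ranks.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1.0  # no ties assumed
    n = len(a)
    obs = ranks[:n].sum()
    counts = {}
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(combo)].sum()
        counts[w] = counts.get(w, 0) + 1
        total += 1
    lo = sum(c for w, c in counts.items() if w <= obs) / total
    hi = sum(c for w, c in counts.items() if w >= obs) / total
    return min(1.0, 2.0 * min(lo, hi)), counts, total


class TestWilcoxonRankSum:
    def test_published_fluctuation_means_complete_separation(self):
        """The six healthy vs six diabetic per-subject σ_h means separate
        completely: exact two-sided p = 2/924."""
        tbl = load_fluctuation_table()
        a = tbl[tbl.group == "healthy"].sigma_nm.to_numpy()
        b = tbl[tbl.group == "diabetic"].sigma_nm.to_numpy()
        res = wilcoxon_rank_sum(a, b)
        assert res.method.endswith("exact")
        assert res.p_value == pytest.approx(2.0 / 924.0, rel=1e-9)
        p_oracle, _, _ = ranksum_enumeration(a, b)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_identical_tied_groups_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_three_vs_three(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.p_value == pytest.approx(2.0 / 20.0, rel=1e-9)

    @pytest.mark.parametrize("n,m", [(4, 5), (6, 6), (7, 3)])
    def test_exact_p_matches_enumeration_oracle(self, n, m, rng):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.5, 1.0, m)
        res = wilcoxon_rank_sum(a, b)
        p_oracle, counts, total = ranksum_enumeration(a, b)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        # the enumerated null distribution is a proper distribution
        assert sum(counts.values()) == total == math.comb(n + m, n)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestLinearFit:
    def test_collinear_data_zero_width_ci(self):
        x = np.arange(5.0)
        res = linear_fit_ci(x, 2.0 * x)
        assert res.statistic == pytest.approx(2.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_hand_computed_ols_slope(self):
        res = linear_fit_ci([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert res.statistic == pytest.approx(0.5)

    def test_slope_invariant_under_sample_order(self, rng):
        x = rng.normal(size=20)
        y = 1.5 * x + rng.normal(size=20)
        perm = rng.permutation(20)
        r1 = linear_fit_ci(x, y)
        r2 = linear_fit_ci(x[perm], y[perm])
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_ci_coverage_near_nominal(self):
        """95% CI covers the true slope in 95% ± 2% of 1000 simulations."""
        rng = np.random.default_rng(77)
        hits = 0
        n_sim = 1000
        x = np.linspace(0.0, 1.0, 20)
        for _ in range(n_sim):
            y = 1.0 + 2.0 * x + rng.normal(0.0, 0.5, x.size)
            res = linear_fit_ci(x, y)
            hits += res.ci_low <= 2.0 <= res.ci_high
        assert abs(hits / n_sim - 0.95) < 0.02

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAncova:
    def test_identical_groups_give_p_one(self, rng):
        x = rng.normal(size=15)
        y = 2.0 * x + rng.normal(size=15)
        res = ancova_slopes(x, y, x, y)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_distinct_slopes_detected(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0.0, 1.0, 20)
        y1 = 1.0 * x + rng.normal(0.0, 0.05, 20)
        y2 = 3.0 * x + rng.normal(0.0, 0.05, 20)
        res = ancova_slopes(x, y1, x, y2)
        assert res.p_value < 0.01

    def test_interaction_f_matches_rss_oracle(self, rng):
        x1 = rng.normal(size=12)
        y1 = 1.0 + 2.0 * x1 + rng.normal(0, 0.3, 12)
        x2 = rng.normal(size=14)
        y2 = 0.5 + 1.0 * x2 + rng.normal(0, 0.3, 14)
        res = ancova_slopes(x1, y1, x2, y2)

        # from-scratch RSS computation with explicit normal equations
        def rss(X, y):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        x = np.concatenate([x1, x2])
        y = np.concatenate([y1, y2])
        g = np.concatenate([np.zeros(12), np.ones(14)])
        ones = np.ones_like(x)
        rss_full = rss(np.column_stack([ones, x, g, x * g]), y)
        rss_red = rss(np.column_stack([ones, x, g]), y)
        f_oracle = (rss_red - rss_full) / (rss_full / (len(x) - 4))
        assert res.statistic == pytest.approx(f_oracle, abs=1e-9)


class TestCorrelations:
    def test_monotone_increasing_spearman_one(self):
        out = correlations([1.0, 2.0, 3.0, 4.0], [2.0, 5.0, 7.0, 20.0])
        assert out["spearman"] == pytest.approx(1.0)

    def test_antitone_both_minus_one(self):
        out = correlations([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert out["pearson"] == pytest.approx(-1.0)
        assert out["spearman"] == pytest.approx(-1.0)

    def test_null_pairs_rarely_exceed_point_three(self):
        exceed = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(size=100)
            y = r.normal(size=100)
            if abs(correlations(x, y)["pearson"]) >= 0.3:
                exceed += 1
        assert exceed <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPooledT:
    def test_identical_groups_give_p_one(self):
        a = [1.0, 2.0, 3.0]
        res = pooled_t_test(a, a)
        assert res.p_value == pytest.approx(1.0)

    def test_one_sd_shift_at_cohort_size_detected(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.0, 1.0, 240)
        b = rng.normal(1.0, 1.0, 240)
        res = pooled_t_test(a, b)
        assert res.p_value < 1e-3

    def test_statistic_antisymmetric_under_swap(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.4, 1.0, 12)
        assert pooled_t_test(a, b).statistic == pytest.approx(
            -pooled_t_test(b, a).statistic)


def _subject(sid, group, sigma_values):
    sr = SubjectRecord(subject_id=sid, group=group, hba1c_pct=5.0)
    for i, s in enumerate(sigma_values):
        sr.cells.append(CellRecord(
            cell_id=f"{sid}_{i}", volume_fl=90.0, surface_um2=140.0,
            sphericity=0.7, hb_g_dl=33.0, hb_pg=29.7, sigma_nm=s,
            mean_dn=0.06))
    return sr


class TestSummarize:
    def test_published_subject_means_reproduce_group_means(self):
        """Averaging the printed per-subject σ_h means gives the printed
        group means: 55.1 nm (healthy) and 46.6 nm (diabetic)."""
        tbl = load_fluctuation_table()
        subjects = [
            _subject(r.subject, r.group, [r.sigma_nm])
            for r in tbl.itertuples()
        ]
        out = summarize_cohort(subjects)
        h = out[(out.group == "healthy") & (out.parameter == "sigma_nm")]
        d = out[(out.group == "diabetic") & (out.parameter == "sigma_nm")]
        assert h.subject_mean.iloc[0] == pytest.approx(55.1, abs=0.05)
        assert d.subject_mean.iloc[0] == pytest.approx(46.6, abs=0.05)

    def test_single_subject_group_mean_is_subject_mean(self):
        s = _subject("x1", "healthy", [50.0, 60.0])
        out = summarize_cohort([s])
        row = out[out.parameter == "sigma_nm"]
        assert row.subject_mean.iloc[0] == pytest.approx(55.0)
        assert row.cell_mean.iloc[0] == pytest.approx(55.0)

    def test_invariant_to_cell_ordering(self):
        a = _subject("x1", "healthy", [40.0, 50.0, 66.0])
        b = _subject("x1", "healthy", [66.0, 40.0, 50.0])
        pd_a = summarize_cohort([a])
        pd_b = summarize_cohort([b])
        assert np.allclose(pd_a.subject_mean, pd_b.subject_mean)
        assert np.allclose(pd_a.cell_sd, pd_b.cell_sd)
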