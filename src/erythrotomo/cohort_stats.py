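"""Cohort-level statistics for two-group red-blood-cell studies.

The primary analysis treats each donor as one data point (the mean over
their ~40 cells) and compares groups with the exact two-sided Wilcoxon
rank-sum test.  Secondary analyses: pooled per-cell Student's t,
ANOVA-based linear fits with 95% CI slopes, a one-way ANCOVA slope-equality
test, and Pearson/Spearman correlations against HbA1c.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .containers import SubjectRecord

__all__ = [
    "StatResult",
    "wilcoxon_rank_sum",
    "linear_fit_ci",
    "ancova_slopes",
    "correlations",
    "pooled_t_test",
    "summarize_cohort",
    "load_fluctuation_table",
]

EXACT_N_MAX = 10  # exact rank-sum enumeration up to this per-group size


@dataclass
class StatResult:
    """A test outcome: statistic, p, optional CI, method tag, group sizes."""

    statistic: float
    p_value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_level: float = float("nan")
    method: str = ""
    n: tuple = ()
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high) \
                and self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")

    def as_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "method": self.method,
            "n": list(self.n),
        }
        d.update(self.extra)
        return d


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      exact: Optional[bool] = None) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration of the rank-sum null distribution when both groups
    have ≤ 10 values and there are no ties (or when forced with
    ``exact=True``); otherwise midranks with the normal approximation and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if exact is None:
        exact = a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return StatResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      method=f"wilcoxon-rank-sum/{method}",
                      n=(int(a.size), int(b.size)))


def linear_fit_ci(x: Sequence[float], y: Sequence[float],
                  level: float = 0.95) -> StatResult:
    """Ordinary least squares y = a + b·x with a t-based CI on the slope.

    The statistic is the slope; the ANOVA F and its p-value ride along in
    ``extra`` together with the intercept.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("x must take at least two distinct values")
    if x.size < 3:
        raise ValueError("need n >= 3 points")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=1.0 - level)
    return StatResult(
        statistic=float(model.params[1]),
        p_value=float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 0.0,
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        ci_level=level,
        method="ols-anova",
        n=(int(x.size),),
        extra={"intercept": float(model.params[0]),
               "f_statistic": float(model.fvalue),
               "r_squared": float(model.rsquared)},
    )


def ancova_slopes(x1, y1, x2, y2) -> StatResult:
    """One-way ANCOVA: F-test of the group × covariate interaction.

    Fits y ~ x + group + x:group and tests the interaction term against the
    parallel-slopes model; the p-value answers whether the two regression
    slopes differ.
    """
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    for x in (x1, x2):
        if np.unique(x).size < 2:
            raise ValueError("each group needs at least two distinct x")
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(x1.size), np.ones(x2.size)])
    X_full = sm.add_constant(np.column_stack([x, g, x * g]))
    X_red = sm.add_constant(np.column_stack([x, g]))
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_den = full.df_resid
    rss_f, rss_r = full.ssr, red.ssr
    if rss_f <= 0:
        F = 0.0 if rss_r <= rss_f + 1e-30 else float("inf")
    else:
        F = (rss_r - rss_f) / 1.0 / (rss_f / df_den)
    p = float(sps.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
    return StatResult(statistic=float(F), p_value=p,
                      method="ancova-interaction-F",
                      n=(int(x1.size), int(x2.size)),
                      extra={"slope_1": float(np.polyfit(x1, y1, 1)[0]),
                             "slope_2": float(np.polyfit(x2, y2, 1)[0]),
                             "df_den": float(df_den)})


def correlations(x, y) -> dict:
    """Pearson and Spearman coefficients with their p-values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    pr = sps.pearsonr(x, y)
    spr = sps.spearmanr(x, y)
    return {
        "pearson": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman": float(spr.statistic),
        "spearman_p": float(spr.pvalue),
        "n": int(x.size),
    }


def pooled_t_test(a, b) -> StatResult:
    """Classic pooled-variance two-sample Student's t, two-sided."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    res = sps.ttest_ind(a, b, equal_var=True)
    return StatResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      method="student-t-pooled",
                      n=(int(a.size), int(b.size)))


_PARAMS = ("volume_fl", "surface_um2", "sphericity", "hb_g_dl", "hb_pg",
           "sigma_nm")


def summarize_cohort(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-group parameter table: mean ± SD of subject means and of cells.

    One row per (group, parameter) with the group mean of subject means,
    the SD across subject means, and the pooled per-cell mean ± SD.
    """
    if not subjects:
        raise ValueError("no subjects")
    rows = []
    groups = sorted({s.group for s in subjects})
    for group in groups:
        grp = [s for s in subjects if s.group == group]
        for p in _PARAMS:
            subj_means = np.array([s.means[p] for s in grp])
            cells = np.array([getattr(c, p) for s in grp for c in s.cells])
            rows.append({
                "group": group,
                "parameter": p,
                "subject_mean": float(subj_means.mean()),
                "subject_sd": float(subj_means.std(ddof=1))
                if subj_means.size > 1 else 0.0,
                "cell_mean": float(cells.mean()),
                "cell_sd": float(cells.std(ddof=1))
                if cells.size > 1 else 0.0,
                "n_subjects": len(grp),
                "n_cells": int(cells.size),
            })
    return pd.DataFrame(rows)


def load_fluctuation_table() -> pd.DataFrame:
    """The published per-subject mean membrane fluctuations (nm).

    Twelve donors (six healthy, six diabetic), ordered within each group by
    increasing HbA1c; these measured values ship with the package as the
    reference fixture for the group comparison.
    """
    ref = importlib.resources.files("erythrotomo").joinpath(
        "data/fluctuation_subject_means.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
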