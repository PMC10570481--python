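"""Statistical layer: ANOVA/Tukey over the K sweep, exact WMW on log-ratios,
cohort-table tests, and cohort-summary reconstruction.

The AUC distributions from the K sweep (7 settings x 100 LOOCV repetitions)
are compared by one-way fixed-effects ANOVA with partial eta squared and
Tukey HSD (Tukey-Kramer for unbalanced groups).  Per-class log-ratio group
differences use the exact Wilcoxon-Mann-Whitney test: the two-sided p is
the exact permutation tail P(|U - n1*n2/2| >= observed) over all
C(n1+n2, n1) group assignments (computed by a dynamic-programming
convolution over midrank subset sums, identical to full enumeration), with
a Monte Carlo fallback above the enumeration cap.  The location shift is
the Hodges-Lehmann estimate (median of pairwise differences) with the
classical distribution-free CI read off the exact null U distribution.
Effect size r = |Z|/sqrt(N) with Z from the tie-corrected normal
approximation.  Cohort metadata tests follow the conventions that reproduce
the reference cohort table: Pearson chi-squared without continuity
correction and the pooled-variance Student's t.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "WmwResult",
    "TTestResult",
    "anova_tukey",
    "wmw_exact",
    "chi_squared",
    "students_t",
    "reconstruct_group_means",
    "per_class_group_comparison",
    "validate_cohort",
    "REFERENCE_COHORT",
]

#: Reference meningioma cohort (N = 27) subtype summaries: per-subtype
#: (n, mean MIB-1 LI %) rows by diagnostic grouping, and 2x2 sex tables.
#: Used to verify that count-weighted reconstruction recovers the published
#: group-level means, and as realistic inputs for the cohort tests.
REFERENCE_COHORT = {
    "grade_subtype_mib1": {
        "low": [(12, 3.1), (3, 7.4), (2, 2.0), (1, 1.0), (1, 0.5)],
        "high": [(6, 5.5), (2, 40.0)],
    },
    "mib1_subtype_mib1": {
        "lt5": [(11, 1.8), (1, 3.0), (2, 2.0), (1, 1.0), (1, 0.5), (2, 3.0)],
        "ge5": [(1, 16.9), (2, 9.7), (4, 6.7), (2, 40.0)],
    },
    # rows = group, cols = (male, female)
    "sex_by_grade": [[8, 11], [5, 3]],
    "sex_by_mib1": [[9, 9], [4, 5]],
}


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False


@dataclass
class TukeyResult:
    table: pd.DataFrame  # pair, mean_diff, p_adj, ci_lower, ci_upper


@dataclass
class WmwResult:
    U: float
    p: float
    r: float
    hl_shift: float
    ci_lower: float
    ci_upper: float
    method: str  # "enumeration" | "monte-carlo"
    n_assignments: int
    seed: int | None = None


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def anova_tukey(
    table: pd.DataFrame, value: str = "auc", group: str = "K"
) -> tuple[AnovaResult, TukeyResult]:
    """One-way fixed-effects ANOVA plus Tukey HSD over ``group`` levels.

    ``table`` is long-format with one row per observation (e.g. one LOOCV
    repetition).  Partial eta squared = SSbetween / (SSbetween + SSwithin).
    All-constant input is flagged degenerate (F undefined).
    """
    groups = [g[value].to_numpy(dtype=float) for _, g in table.groupby(group)]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if min(len(g) for g in groups) < 2:
        raise ValueError("ANOVA requires at least 2 values per group")
    x = np.concatenate(groups)
    grand = x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(x) - len(groups)
    if ss_within == 0 and ss_between == 0:
        anova = AnovaResult(np.nan, df_b, df_w, np.nan, np.nan, degenerate=True)
    else:
        F = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
        p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
        anova = AnovaResult(
            F=float(F), df_between=df_b, df_within=df_w, p=p,
            partial_eta_sq=float(ss_between / (ss_between + ss_within)),
        )
    tk = pairwise_tukeyhsd(x, table[group].to_numpy(), alpha=0.05)
    frame = pd.DataFrame(
        data=tk.summary().data[1:], columns=tk.summary().data[0]
    ).rename(
        columns={
            "group1": "a", "group2": "b", "meandiff": "mean_diff",
            "p-adj": "p_adj", "lower": "ci_lower", "upper": "ci_upper",
        }
    )
    return anova, TukeyResult(table=frame[["a", "b", "mean_diff", "p_adj",
                                           "ci_lower", "ci_upper"]])


# ---------------------------------------------------------------------------
# Exact Wilcoxon-Mann-Whitney


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    return float(
        (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    )


def _exact_ranksum_distribution(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Counts of each doubled-rank-sum value over all size-n1 subsets.

    ``ranks2`` are doubled midranks (integers).  Returns ``counts`` where
    ``counts[s]`` is the number of subsets of size n1 whose doubled midranks
    sum to s.  Equivalent to enumerating all C(n, n1) assignments.
    """
    ranks2 = np.asarray(ranks2, dtype=np.int64)
    smax = int(np.sort(ranks2)[-n1:].sum())
    dp = np.zeros((n1 + 1, smax + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(n1, 0, -1):
            dp[j, r:] += dp[j - 1, : smax + 1 - r]
    return dp[n1]


def wmw_exact(
    x: Sequence[float],
    y: Sequence[float],
    enumeration_cap: int = 3_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
    ci: float = 95.0,
) -> WmwResult:
    """Exact two-sided Wilcoxon-Mann-Whitney test with shift estimate and CI.

    When C(n1+n2, n1) <= ``enumeration_cap`` the two-sided p is the exact
    tail proportion of assignments with |U - n1*n2/2| >= observed;
    otherwise it is a Monte Carlo permutation estimate over ``n_mc`` draws
    (the observed assignment counted in the numerator and denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    u_obs = _u_statistic(x, y)
    mid = n1 * n2 / 2.0
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n_total = comb(n, n1)
    used_seed: int | None = None

    if n_total <= enumeration_cap:
        method = "enumeration"
        ranks2 = np.rint(2.0 * ranks).astype(np.int64)
        counts = _exact_ranksum_distribution(ranks2, n1)
        # doubled U for each doubled rank-sum s: u2 = s - n1*(n1+1)
        s_vals = np.arange(len(counts))
        u2 = s_vals - n1 * (n1 + 1)
        dev = np.abs(u2 - n1 * n2)  # doubled |U - mid|
        dev_obs = np.rint(2.0 * abs(u_obs - mid)).astype(np.int64)
        p = float(counts[dev >= dev_obs - 1e-9].sum() / counts.sum())
        n_assign = n_total
        null_u2_counts = (u2, counts)
    else:
        method = "monte-carlo"
        used_seed = seed
        rng = np.random.default_rng(seed)
        hits = 0
        dev_obs_f = abs(u_obs - mid)
        block = 20_000
        done = 0
        rsum_const = n1 * (n1 + 1) / 2.0
        while done < n_mc:
            b = min(block, n_mc - done)
            keys = rng.random((b, n))
            idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
            rs = ranks[idx].sum(axis=1)
            u = rs - rsum_const
            hits += int((np.abs(u - mid) >= dev_obs_f - 1e-9).sum())
            done += b
        p = (hits + 1) / (n_mc + 1)
        n_assign = n_mc
        null_u2_counts = None

    # tie-corrected normal approximation for the effect size r = |Z|/sqrt(N)
    _, t_counts = np.unique(combined, return_counts=True)
    tie_term = ((t_counts**3 - t_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u_obs - mid) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    r_eff = abs(z) / np.sqrt(n)

    # Hodges-Lehmann shift of x relative to y, with the distribution-free CI
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    alpha = 1.0 - ci / 100.0
    if null_u2_counts is not None:
        u2_vals, counts = null_u2_counts
        cdf = np.cumsum(counts) / counts.sum()
        # k = smallest U value with P(U <= k) >= alpha/2 on the doubled scale
        k2 = u2_vals[np.searchsorted(cdf, alpha / 2.0)]
        k = int(np.floor(k2 / 2.0))
    else:
        k = int(np.floor(mid + np.sqrt(sigma2) * sps.norm.ppf(alpha / 2.0)))
    k = int(np.clip(k, 0, n1 * n2 - 1))
    lo = float(diffs[k])
    hi = float(diffs[n1 * n2 - 1 - k])
    return WmwResult(
        U=u_obs, p=float(min(p, 1.0)), r=float(min(r_eff, 1.0)),
        hl_shift=hl, ci_lower=lo, ci_upper=hi,
        method=method, n_assignments=n_assign, seed=used_seed,
    )


# ---------------------------------------------------------------------------
# Cohort-table tests


def chi_squared(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    The uncorrected convention is fixed because it reproduces the reference
    cohort's sex-ratio p-values (.33 and .78).
    """
    t = np.asarray(table)
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must contain non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined with a zero marginal")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def students_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided pooled-variance two-sample Student's t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    df = len(x) + len(y) - 2
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        equal = x.mean() == y.mean()
        return TTestResult(
            t=0.0 if equal else np.inf, df=df, p=1.0 if equal else 0.0,
            degenerate=True,
        )
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def reconstruct_group_means(rows: Sequence[tuple[int, float]]) -> float:
    """Count-weighted mean of per-subtype (n, mean) rows, to one decimal.

    Reconstructs a group-level summary from its subtype breakdown, e.g. the
    group mean MIB-1 LI from per-subtype means.
    """
    if len(rows) == 0:
        raise ValueError("need at least one (n, mean) row")
    ns = np.array([r[0] for r in rows], dtype=float)
    means = np.array([r[1] for r in rows], dtype=float)
    if (ns < 1).any():
        raise ValueError("every subtype row must have n >= 1")
    return round(float((ns * means).sum() / ns.sum()), 1)


# ---------------------------------------------------------------------------
# Per-class comparisons


def per_class_group_comparison(
    log_ratios: np.ndarray,
    labels: Sequence[int],
    correction: str | None = None,
    enumeration_cap: int = 3_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact WMW on each class's log-ratios between the two groups.

    ``log_ratios`` is (n_subjects, K); ``labels`` codes the positive group
    as 1.  The shift is group-1 minus group-0, so a positive Hodges-Lehmann
    estimate means the class is over-occupied in the positive (high-grade /
    high-MIB-1) group.  No multiple-testing correction by default;
    ``correction="holm"`` adjusts the K p-values.
    """
    F = np.asarray(log_ratios, dtype=float)
    y = np.asarray(labels).astype(int)
    if F.shape[0] != len(y):
        raise ValueError("log_ratios and labels must align")
    rows = []
    for k in range(F.shape[1]):
        res = wmw_exact(
            F[y == 1, k], F[y == 0, k],
            enumeration_cap=enumeration_cap, seed=seed + k,
        )
        rows.append(
            {
                "class": k + 1, "U": res.U, "p": res.p, "r": res.r,
                "hl_shift": res.hl_shift, "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper, "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    if correction == "holm":
        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out


# ---------------------------------------------------------------------------
# Cohort-table validation


def validate_cohort(cohort: pd.DataFrame, mib1_threshold: float = 5.0) -> None:
    """Check cohort-table invariants; raise ValueError on violation."""
    required = {"subject_id", "who_grade", "subtype", "mib1_li_percent",
                "age", "sex", "grade_group", "mib1_group"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    low_ok = (cohort.grade_group == "low") == (cohort.who_grade == "I")
    if not low_ok.all():
        raise ValueError("grade_group must be 'low' exactly for WHO grade I")
    ge5 = (cohort.mib1_group == "ge5") == (cohort.mib1_li_percent >= mib1_threshold)
    if not ge5.all():
        raise ValueError(
            f"mib1_group must be 'ge5' exactly when MIB-1 LI >= {mib1_threshold}"
        )
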