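"""Group-comparison statistics on per-animal metric tables.

Two-group comparisons use an unpaired two-sided t-test; when an F-test
on the sample variances rejects equality at alpha = 0.05 the Welch
(unequal-variance) form with Welch-Satterthwaite degrees of freedom is
used instead, and the branch taken is always reported.  More than two
groups are compared with one-way fixed-effects ANOVA followed by
pairwise pooled-variance t-tests with Bonferroni correction over the
requested comparisons.  Summaries report mean ± SEM (SD/sqrt(n), sample
SD with n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_two", "anova_bonferroni", "summarize",
           "variance_f_test"]


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test: str  # student_t | welch_t | anova | anova_bonferroni_pair
    statistic: float
    df: float
    p_value: float
    group_means: list[float] = field(default_factory=list)
    group_sems: list[float] = field(default_factory=list)
    group_ns: list[int] = field(default_factory=list)
    p_adjusted: float | None = None
    comparison: tuple[int, int] | None = None


def summarize(values) -> tuple[float, float, int]:
    """(mean, SEM, n); SEM = sample SD / sqrt(n), defined as 0 for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    n = int(v.size)
    sem = 0.0 if n == 1 else float(v.std(ddof=1) / np.sqrt(n))
    return float(v.mean()), sem, n


def variance_f_test(a, b) -> tuple[float, float]:
    """Two-sided F-test of equal variances; returns (F, p).

    F is the larger sample variance over the smaller; p doubles the
    upper tail (capped at 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0, 1.0
    if va >= vb:
        num_var, num_df, den_var, den_df = va, a.size - 1, vb, b.size - 1
    else:
        num_var, num_df, den_var, den_df = vb, b.size - 1, va, a.size - 1
    if den_var == 0:
        return float("inf"), 0.0
    f = num_var / den_var
    p = min(1.0, 2.0 * float(sps.f.sf(f, num_df, den_df)))
    return float(f), p


def compare_two(group_a, group_b, alpha_variance: float = 0.05) -> ComparisonResult:
    """Unpaired two-sided t-test between two groups of per-animal values.

    An F-test on the variances at ``alpha_variance`` chooses between the
    pooled-variance Student branch and the Welch branch; the ``test``
    field reports which one ran.  Two identical constant groups give
    t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    mean_a, sem_a, na = summarize(a)
    mean_b, sem_b, nb = summarize(b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if mean_a == mean_b:
            return ComparisonResult(
                "student_t", 0.0, float(na + nb - 2), 1.0,
                [mean_a, mean_b], [sem_a, sem_b], [na, nb],
            )
        raise ValueError("zero variance in both groups with unequal means")
    _, p_var = variance_f_test(a, b)
    welch = p_var < alpha_variance
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return ComparisonResult(
        "welch_t" if welch else "student_t",
        float(res.statistic),
        df,
        float(res.pvalue),
        [mean_a, mean_b],
        [sem_a, sem_b],
        [na, nb],
    )


def anova_bonferroni(
    groups: list, comparisons: list[tuple[int, int]] | None = None
) -> list[ComparisonResult]:
    """One-way ANOVA plus Bonferroni-corrected pairwise comparisons.

    The first result is the omnibus ANOVA (F, df reported as the
    between-groups df; within df in ``group_ns``-derivable form).  Each
    requested pair then gets a pooled-MSwithin t-test whose raw p is
    multiplied by the number of requested comparisons, capped at 1.  If
    ``comparisons`` is None all pairs are compared.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 3:
        raise ValueError("need at least 3 groups (use compare_two for 2)")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    if comparisons is None:
        comparisons = [(i, j) for i in range(k) for j in range(i + 1, k)]
    ns = [a.size for a in arrays]
    n_total = sum(ns)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrays))
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
        p_f = 1.0 if ms_between == 0 else 0.0
    else:
        f_stat = float(ms_between / ms_within)
        p_f = float(sps.f.sf(f_stat, df_between, df_within))
    means = [float(a.mean()) for a in arrays]
    sems = [summarize(a)[1] for a in arrays]
    out = [
        ComparisonResult(
            "anova", f_stat, float(df_between), p_f, means, sems, list(ns)
        )
    ]
    m = len(comparisons)
    for (i, j) in comparisons:
        se = np.sqrt(ms_within * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            t = 0.0 if means[i] == means[j] else float("inf")
            p_raw = 1.0 if means[i] == means[j] else 0.0
        else:
            t = float((means[i] - means[j]) / se)
            p_raw = float(2.0 * sps.t.sf(abs(t), df_within))
        out.append(
            ComparisonResult(
                "anova_bonferroni_pair",
                t,
                float(df_within),
                p_raw,
                [means[i], means[j]],
                [sems[i], sems[j]],
                [ns[i], ns[j]],
                p_adjusted=min(1.0, p_raw * m),
                comparison=(i, j),
            )
        )
    return out
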