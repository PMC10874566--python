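"""Group statistics in the conventions of the source analyses.

Two-group comparisons use the pooled-variance (Student) unpaired t-test —
the printed df for n = 5 vs n = 10 mice is 13 = n1 + n2 - 2, which fixes the
pooled form over Welch.  Multi-group comparisons use a one-way ANOVA with
protected Bonferroni post hoc pairwise tests: each pairwise t uses the
pooled within-group mean square with df_within, and raw p-values are scaled
by the number of comparisons m = k(k-1)/2, capped at 1.

The statistical unit is the mouse: slice-level values should be averaged per
mouse before calling these functions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "unpaired_t",
    "anova_bonferroni",
    "significance_stars",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n1: int
    n2: int


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: list[tuple[int, int, float, float, float]]  # (i, j, t, p_raw, p_bonf)


def unpaired_t(x, y) -> TTestResult:
    """Two-sided Student (pooled-variance) unpaired t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = n1 + n2 - 2
    mean_diff = float(x.mean() - y.mean())
    ss = float(((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
    if ss == 0.0:
        if mean_diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, n1=n1, n2=n2)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    sp2 = ss / df
    t = mean_diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, mean_diff=mean_diff, n1=n1, n2=n2)


def anova_bonferroni(groups) -> AnovaResult:
    """One-way ANOVA with protected Bonferroni pairwise post hoc tests."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("need at least 3 groups (use unpaired_t for 2)")
    ns = [len(g) for g in groups]
    if any(n < 2 for n in ns):
        raise ValueError("each group needs at least 2 observations")
    N = sum(ns)
    grand = float(np.concatenate(groups).mean())
    ss_between = sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups))
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_between = k - 1
    df_within = N - k
    ms_between = ss_between / df_between
    if ss_within == 0.0:
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            raise ValueError("zero within-group variance with unequal means: F undefined")
    else:
        ms_within = ss_within / df_within
        F = ms_between / ms_within
        p = float(sps.f.sf(F, df_between, df_within))

    m = k * (k - 1) // 2
    pairwise = []
    mse = ss_within / df_within if ss_within > 0 else 0.0
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        diff = float(gi.mean() - gj.mean())
        if mse == 0.0:
            t_ij, p_raw = (0.0, 1.0) if diff == 0.0 else (math.inf, 0.0)
        else:
            t_ij = diff / math.sqrt(mse * (1.0 / len(gi) + 1.0 / len(gj)))
            p_raw = 2.0 * float(sps.t.sf(abs(t_ij), df_within))
        pairwise.append((i, j, t_ij, p_raw, min(1.0, m * p_raw)))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p, pairwise=pairwise)


def significance_stars(p: float) -> str:
    """Figure-legend star labels: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
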