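"""Statistical layer: exact tests, ANOVA variants and summary conventions.

Each test here states its exact contract, because names like "Fisher's
exact test" or "nested ANOVA" alone underdetermine the computation:

* Fisher's exact test, two-sided by the probability-mass definition (the sum
  of hypergeometric probabilities of all tables, at fixed margins, no more
  probable than the observed one), computed by exact integer enumeration;
* Bonferroni adjustment with the family size m always explicit;
* one-way ANOVA followed by Tukey's HSD;
* two-level nested ANOVA testing the group effect against the among-unit
  (embryo) mean square — the correct error stratum when several
  measurements are taken per embryo;
* unpaired two-sided t-test (pooled-variance Student form by default,
  Welch by flag);
* box-plot summaries with whiskers at the data min/max (the study's
  convention) or at 1.5 IQR with outliers listed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """Uniform container for a single test outcome."""

    test: str
    statistic: float
    raw_p: float
    df: Optional[tuple] = None
    adjusted_p: Optional[float] = None
    adjust_method: Optional[str] = None
    m: Optional[int] = None
    effect: Optional[dict] = None
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic, "df": self.df,
            "raw_p": self.raw_p, "adjusted_p": self.adjusted_p,
            "adjust_method": self.adjust_method, "m": self.m,
            "effect": self.effect, "flags": self.flags,
        }


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher's exact test of independence on a 2x2 table.

    With margins fixed, the table is determined by its top-left cell a; the
    probability of each candidate table is hypergeometric with integer
    numerator C(r1, a) C(r2, c1 - a) over the common denominator C(n, c1).
    The two-sided p sums the probabilities of all tables whose probability
    does not exceed the observed one. Numerator comparisons are done in
    exact integer arithmetic, so ties are handled without floating-point
    ambiguity. The reported effect is the sample odds ratio.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integer counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("Fisher's exact test requires all margins positive")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = numerators[a - lo]
    num_sum = sum(x for x in numerators if x <= observed)
    p = num_sum / comb(n, c1)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return StatResult(test="fisher_exact_2x2", statistic=float(odds),
                      raw_p=float(min(p, 1.0)),
                      effect={"odds_ratio": float(odds)})


def bonferroni(p_values, m: Optional[int] = None):
    """Bonferroni adjustment: p -> min(1, m * p), m = family size.

    ``m`` defaults to the number of p-values and must be at least that.
    """
    ps = np.asarray(p_values, dtype=float)
    if np.any((ps < 0) | (ps > 1) | ~np.isfinite(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = ps.size
    if m < ps.size:
        raise ValueError("family size m must be >= the number of p-values")
    return np.minimum(1.0, m * ps)


def anova_tukey(groups: dict) -> tuple:
    """One-way ANOVA followed by Tukey's HSD over named groups.

    ``groups`` maps label -> 1D array of values. Returns ``(anova,
    pairwise)`` where pairwise is a list of StatResults, one per unordered
    pair, with Tukey-adjusted p-values from the studentized-range
    distribution. Degenerate data (zero variance everywhere) is flagged
    with undefined p rather than raising.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], float) for k in labels]
    if any(len(x) < 2 for x in arrays):
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        res = StatResult(test="anova_oneway", statistic=0.0, raw_p=np.nan,
                         flags=["degenerate: zero variance in all groups"])
        return res, []
    F, p = sps.f_oneway(*arrays)
    df = (len(labels) - 1, sum(len(x) for x in arrays) - len(labels))
    anova = StatResult(test="anova_oneway", statistic=float(F),
                       raw_p=float(p), df=df)
    if np.all([np.allclose(x, np.mean(x)) for x in arrays]) and np.isnan(F):
        anova.flags.append("degenerate within-group variance")
        return anova, []
    hsd = sps.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise.append(StatResult(
                test="tukey_hsd", statistic=float(hsd.statistic[i, j]),
                raw_p=float(hsd.pvalue[i, j]), adjusted_p=float(hsd.pvalue[i, j]),
                adjust_method="tukey",
                effect={"pair": (labels[i], labels[j]),
                        "mean_difference": float(np.mean(arrays[i])
                                                 - np.mean(arrays[j]))}))
    return anova, pairwise


def nested_anova(design: pd.DataFrame, group_col: str = "group",
                 unit_col: str = "unit", value_col: str = "value") -> StatResult:
    """Two-level nested ANOVA: group effect tested against units-in-groups.

    With several measurements per unit (embryo) and units nested in groups
    (genotypes), the group mean square is compared with the among-unit
    mean square, not the residual: F = MS_group / MS_unit(group) with
    df = (g - 1, total units - g). Unbalanced designs use the same sums of
    squares weighted by observation counts. A group with a single unit has
    no within-group unit variation and raises.
    """
    df = design[[group_col, unit_col, value_col]].dropna()
    groups = df.groupby(group_col)
    g = groups.ngroups
    if g < 2:
        raise ValueError("need at least 2 groups")
    units_per_group = groups[unit_col].nunique()
    if (units_per_group < 2).any():
        bad = units_per_group[units_per_group < 2].index.tolist()
        raise ValueError(f"nested ANOVA needs >= 2 units per group; got a "
                         f"single unit in group(s) {bad}")
    grand = df[value_col].mean()
    ss_group = float(sum(len(sub) * (sub[value_col].mean() - grand) ** 2
                         for _, sub in groups))
    ss_unit = 0.0
    for _, sub in groups:
        gmean = sub[value_col].mean()
        for _, usub in sub.groupby(unit_col):
            ss_unit += len(usub) * (usub[value_col].mean() - gmean) ** 2
    df1 = g - 1
    df2 = int(units_per_group.sum()) - g
    ms_group = ss_group / df1
    ms_unit = ss_unit / df2
    if ms_unit == 0:
        return StatResult(test="nested_anova", statistic=np.inf, raw_p=0.0,
                          df=(df1, df2), flags=["zero among-unit variance"])
    F = ms_group / ms_unit
    p = float(sps.f.sf(F, df1, df2))
    return StatResult(test="nested_anova", statistic=float(F), raw_p=p,
                      df=(df1, df2),
                      effect={"ms_group": ms_group, "ms_unit": ms_unit})


def ttest_unpaired(group_a, group_b, welch: bool = False) -> StatResult:
    """Unpaired two-sided t-test (pooled-variance Student form by default)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return StatResult(test="ttest_unpaired", statistic=0.0, raw_p=1.0,
                              flags=["degenerate: zero variance, equal means"])
        return StatResult(test="ttest_unpaired", statistic=np.inf, raw_p=0.0,
                          flags=["degenerate: zero variance, unequal means"])
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return StatResult(test="ttest_welch" if welch else "ttest_unpaired",
                      statistic=float(res.statistic), raw_p=float(res.pvalue),
                      df=(float(df),),
                      effect={"mean_difference": float(a.mean() - b.mean())})


def box_summary(values, whiskers: str = "minmax") -> dict:
    """Box-plot summary statistics.

    ``whiskers="minmax"`` places whiskers at the data extremes (the study's
    box-plot convention) and reports no outliers; ``whiskers="tukey"`` uses
    the 1.5 IQR rule and lists points beyond the fences as outliers.
    Quartiles use linear interpolation.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 1:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    if whiskers == "minmax":
        lo, hi = float(x.min()), float(x.max())
        outliers = []
    elif whiskers == "tukey":
        iqr = q75 - q25
        lo_f, hi_f = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inside = x[(x >= lo_f) & (x <= hi_f)]
        lo, hi = float(inside.min()), float(inside.max())
        outliers = sorted(float(v) for v in x[(x < lo_f) | (x > hi_f)])
    else:
        raise ValueError("whiskers must be 'minmax' or 'tukey'")
    return {"q25": float(q25), "median": float(med), "q75": float(q75),
            "whisker_low": lo, "whisker_high": hi, "outliers": outliers,
            "n": int(x.size)}
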