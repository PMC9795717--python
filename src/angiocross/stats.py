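"""Statistical comparisons used across the pipeline.

Group comparisons of morphometric endpoints use two-sided Mann–Whitney
U tests with Bonferroni adjustment; curvature distributions are
compared with the two-sample Kolmogorov–Smirnov test; the 2D
orientation analysis uses a two-way ANOVA (day × location) with
Bonferroni-corrected post-hoc location contrasts per day; and the
coverage–volume relation is an ordinary least-squares line.

A dataset pair is called significant when p < ``ALPHA`` and, in the
colocalization analysis, correlated when Pearson r > 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class StatResult:
    statistic: float
    p: float
    method: str
    n: tuple
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        return bool(p < ALPHA)


def bonferroni(p: float, m: int) -> float:
    """min(1, m·p); the number of comparisons m is always explicit."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, m * p))


def mann_whitney(a, b, m_comparisons: int = 1) -> StatResult:
    """Two-sided Mann–Whitney U with Bonferroni adjustment.

    The exact null distribution is used when both groups have n ≤ 8 and
    there are no ties; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return StatResult(
            statistic=a.size * b.size / 2.0,
            p=1.0,
            p_adjusted=1.0,
            method="mann-whitney-u (all tied)",
            n=(a.size, b.size),
        )
    ties = np.unique(pooled).size < pooled.size
    exact = a.size <= 8 and b.size <= 8 and not ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return StatResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        p_adjusted=bonferroni(float(res.pvalue), m_comparisons),
        method=f"mann-whitney-u ({'exact' if exact else 'normal approx.'})",
        n=(a.size, b.size),
    )


def ks_two_sample(a, b) -> StatResult:
    """Two-sample Kolmogorov–Smirnov: D = sup |ECDF_a − ECDF_b|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples need at least one observation")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return StatResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        method="ks-2-sample (asymptotic)",
        n=(a.size, b.size),
    )


def two_way_anova_bonferroni(
    values, factor_day, factor_location
) -> dict[str, StatResult]:
    """Two-way ANOVA (day × location) plus per-day location post hocs.

    Type-II sums of squares (robust to mild imbalance).  Post-hoc
    contrasts are two-sample t tests of location within each day,
    Bonferroni-adjusted over the number of days.  Returns a dict with
    keys ``day``, ``location``, ``interaction`` and ``posthoc_day_<d>``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "day": pd.Categorical(factor_day),
            "location": pd.Categorical(factor_location),
        }
    )
    counts = df.groupby(["day", "location"], observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"empty design cell(s): {list(empty.index)}")
    if df["day"].nunique() < 2 or df["location"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    if df["value"].std() == 0:
        res = StatResult(
            statistic=np.nan, p=np.nan, method="two-way anova (zero variance)",
            n=(len(df),), extra={"zero_variance": True},
        )
        return {"day": res, "location": res, "interaction": res}

    model = smf.ols("value ~ C(day) * C(location)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out: dict[str, StatResult] = {}
    for key, row_name in (
        ("day", "C(day)"),
        ("location", "C(location)"),
        ("interaction", "C(day):C(location)"),
    ):
        out[key] = StatResult(
            statistic=float(table.loc[row_name, "F"]),
            p=float(table.loc[row_name, "PR(>F)"]),
            method="two-way anova (type II)",
            n=(len(df),),
            extra={"df": float(table.loc[row_name, "df"])},
        )
    days = list(df["day"].cat.categories)
    m = len(days)
    for d in days:
        sub = df[df["day"] == d]
        groups = [g["value"].to_numpy() for _, g in sub.groupby("location", observed=True)]
        if len(groups) != 2:
            raise ValueError("post-hoc contrasts expect exactly two locations")
        t, p = sps.ttest_ind(groups[0], groups[1])
        out[f"posthoc_day_{d}"] = StatResult(
            statistic=float(t),
            p=float(p),
            p_adjusted=bonferroni(float(p), m),
            method="t-test location within day (Bonferroni)",
            n=(len(groups[0]), len(groups[1])),
        )
    return out


def linear_fit(x, y) -> StatResult:
    """Ordinary least squares y = slope·x + intercept.

    Returns slope as the statistic with intercept/r² in ``extra``.
    A constant y gives slope 0 and r² = 0; a constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope undefined")
    if np.all(y == y[0]):
        return StatResult(
            statistic=0.0, p=1.0, method="ols", n=(x.size,),
            extra={"intercept": float(y[0]), "r2": 0.0},
        )
    res = sps.linregress(x, y)
    return StatResult(
        statistic=float(res.slope),
        p=float(res.pvalue),
        method="ols",
        n=(x.size,),
        extra={"intercept": float(res.intercept), "r2": float(res.rvalue**2)},
    )
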