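"""Group-comparison statistics: t-tests, one-way ANOVA + Tukey HSD, and the
significance-star convention.

"Standard t-test" is read as Student's unpaired two-sided test (pooled
variance); Welch and paired variants are exposed as flags.  A
summary-statistics t-test supports re-analysis of published mean/SD/n rows.
ANOVA is one-way, with Tukey HSD adjusted pairwise p-values from the
studentized-range distribution.  No multiple-testing correction is applied
beyond Tukey.

Stars: * p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001 (inclusive
thresholds); p>0.05 is "ns".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class StatResult:
    test: str
    statistic: float
    df: float | tuple
    p_value: float
    stars: str = field(default="ns")
    pairwise: pd.DataFrame | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value):
            self.stars = significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Map a p-value to the plot-star convention (inclusive thresholds)."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p-value {p} outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InsufficientDataError(f"sample {name} needs n >= 2")
    return arr


def t_test(a, b, paired: bool = False, welch: bool = False) -> StatResult:
    """Two-sided t-test between two samples (Student pooled by default)."""
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if paired:
        if a.size != b.size:
            raise InsufficientDataError("paired test requires equal sample sizes")
        res = sps.ttest_rel(a, b)
        name = "paired t-test"
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        name = "Welch t-test" if welch else "Student t-test"
    stat, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
    if not np.isfinite(stat):  # zero-variance degenerate input
        same = np.allclose(a.mean(), b.mean())
        stat = 0.0 if same else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if same else 0.0
        return StatResult(name, stat, dof, p, note="degenerate: zero variance")
    return StatResult(name, stat, dof, p)


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> StatResult:
    """t-test from published summary statistics (mean, SD, n per group);
    agrees exactly with :func:`t_test` on raw samples with these summaries."""
    if sd1 < 0 or sd2 < 0:
        raise DomainError("SDs must be >= 0")
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("summary t-test needs n >= 2 per group")
    if sd1 == 0 and sd2 == 0:
        same = np.isclose(mean1, mean2)
        return StatResult(
            "summary t-test",
            0.0 if same else np.inf * np.sign(mean1 - mean2),
            float(n1 + n2 - 2),
            1.0 if same else 0.0,
            note="degenerate: zero variance",
        )
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    dof = n1 + n2 - 2 if not welch else _welch_df(sd1, n1, sd2, n2)
    return StatResult("summary t-test", float(res.statistic), float(dof), float(res.pvalue))


def _welch_df(sd1: float, n1: int, sd2: float, n2: int) -> float:
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def anova_tukey(groups: list, names: list[str] | None = None) -> StatResult:
    """One-way ANOVA with Tukey HSD post hoc pairwise comparisons.

    The ANOVA F/p come from the standard one-way decomposition; pairwise
    adjusted p-values use the studentized-range distribution.  For identical
    constant groups the degenerate F = 0 / p = 1 is returned.
    """
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    samples = [_as_sample(g, f"group{i}") for i, g in enumerate(groups)]
    if names is None:
        names = [f"group{i}" for i in range(len(samples))]
    k = len(samples)
    n_total = sum(s.size for s in samples)
    dof = (k - 1, n_total - k)
    if all(s.std(ddof=1) == 0 for s in samples) and all(
        np.allclose(s.mean(), samples[0].mean()) for s in samples
    ):
        pairwise = pd.DataFrame(
            [
                {"group_a": names[i], "group_b": names[j],
                 "mean_diff": 0.0, "p_adj": 1.0, "stars": "ns"}
                for i in range(k) for j in range(i + 1, k)
            ]
        )
        return StatResult("one-way ANOVA + Tukey", 0.0, dof, 1.0, pairwise=pairwise,
                          note="degenerate: identical groups")
    f_res = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            p_adj = float(hsd.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": p_adj,
                    "stars": significance_stars(min(max(p_adj, 0.0), 1.0)),
                }
            )
    return StatResult(
        "one-way ANOVA + Tukey",
        float(f_res.statistic),
        dof,
        float(f_res.pvalue),
        pairwise=pd.DataFrame(rows),
    )


def group_table(
    df: pd.DataFrame, group_col: str, value_col: str
) -> StatResult:
    """Convenience: compare a value column across the groups of a table."""
    groups = [g[value_col].to_numpy(float) for _, g in df.groupby(group_col, sort=False)]
    names = [str(name) for name, _ in df.groupby(group_col, sort=False)]
    if len(groups) == 2:
        return t_test(groups[0], groups[1])
    return anova_tukey(groups, names=names)
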