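"""Cohort statistics: the normality-driven test-selection procedure.

Group comparisons follow the common clinical-reporting recipe: per-group
Shapiro–Wilk at α = 0.05 decides between one-way ANOVA (all groups normal)
and Kruskal–Wallis; categorical contingency tables use chi-square, or
Fisher's exact test when any expected cell is below five.  Correlations
select Pearson when both margins pass Shapiro–Wilk and Spearman otherwise.
All tests are two-sided; no multiple-testing correction is applied.  Group
summaries are formatted to match the distributional decision: mean ± SEM
when normal, median (IQR) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "compare_groups",
    "correlate",
    "group_assign",
    "AGE_GROUP_BOUNDS",
]

NORMALITY_ALPHA = 0.05

#: Seven age groups; pediatric bounds are half-open [lo, hi).  The adult
#: boundary follows "18-40, 41-60": the 18-40 group is closed at 40 and any
#: age in (40, 41) falls to "41-60" (flagged in output metadata, since the
#: source notation is inconsistent).
AGE_GROUP_BOUNDS = (
    ("<1", 0.0, 1.0),
    ("1-<2", 1.0, 2.0),
    ("2-<7", 2.0, 7.0),
    ("7-<12", 7.0, 12.0),
    ("12-<18", 12.0, 18.0),
    ("18-40", 18.0, 40.0),
    ("41-60", 40.0, 60.0),
)


@dataclass
class GroupComparisonResult:
    test: str                       # ANOVA | Kruskal-Wallis | chi-square | Fisher-exact
    statistic: float
    p_value: float
    normal: dict = field(default_factory=dict)      # group -> Shapiro-Wilk p
    all_normal: bool | None = None
    summaries: dict = field(default_factory=dict)   # group -> formatted summary
    n: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


class CorrelationResult(NamedTuple):
    coefficient: float
    p_value: float
    method: str


def _summary(values: np.ndarray, normal: bool) -> str:
    if normal:
        sem = values.std(ddof=1) / np.sqrt(len(values))
        return f"{values.mean():.3g} ± {sem:.2g}"
    q1, q3 = np.percentile(values, [25, 75])
    return f"{np.median(values):.3g} ({q3 - q1:.2g})"


def compare_groups(groups, kind: str = "continuous") -> GroupComparisonResult:
    """Compare data across groups with the normality-driven decision rule.

    Parameters
    ----------
    groups
        For ``kind="continuous"``: a mapping of group label to 1-D values
        (or a sequence of arrays).  Groups with fewer than three usable
        observations are excluded with a warning.  For
        ``kind="categorical"``: a complete contingency table (2-D array or
        DataFrame, groups × categories).
    """
    if kind == "categorical":
        table = np.asarray(groups, dtype=float)
        if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError("categorical comparison needs a groups × categories table")
        chi2, p, dof, expected = stats.chi2_contingency(table)
        if np.any(expected < 5):
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table)
                return GroupComparisonResult(test="Fisher-exact", statistic=np.nan,
                                             p_value=float(p))
            warnings.warn(
                "expected cell count < 5 in a table larger than 2x2; "
                "chi-square approximation may be poor",
                stacklevel=2,
            )
        return GroupComparisonResult(test="chi-square", statistic=float(chi2),
                                     p_value=float(p))
    if kind != "continuous":
        raise ValueError(f"unknown kind {kind!r}")

    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(f"group{i}", g) for i, g in enumerate(groups)]
    if len(items) < 2:
        raise ValueError("need at least two groups")
    clean, excluded = [], []
    for label, values in items:
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 3:
            warnings.warn(f"group {label!r} has < 3 observations; excluded", stacklevel=2)
            excluded.append(label)
        else:
            clean.append((label, v))
    if len(clean) < 2:
        raise ValueError("fewer than two groups with >= 3 observations remain")

    normal_p = {}
    for label, v in clean:
        if np.ptp(v) == 0:
            normal_p[label] = 0.0  # constant data: treat as non-normal
        else:
            normal_p[label] = float(stats.shapiro(v).pvalue)
    all_normal = all(p > NORMALITY_ALPHA for p in normal_p.values())
    arrays = [v for _, v in clean]
    if all_normal:
        stat, p = stats.f_oneway(*arrays)
        test = "ANOVA"
    else:
        stat, p = stats.kruskal(*arrays)
        test = "Kruskal-Wallis"
    if np.isnan(p):
        # degenerate inputs (e.g. identical groups) carry no evidence
        # against the null; report the non-significant limit
        p = 1.0
    return GroupComparisonResult(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        normal=normal_p,
        all_normal=all_normal,
        summaries={label: _summary(v, all_normal) for label, v in clean},
        n={label: len(v) for label, v in clean},
        excluded=excluded,
    )


def correlate(x, y, force: str = "auto") -> CorrelationResult:
    """Pearson or Spearman correlation selected by marginal normality.

    ``force="auto"`` picks Pearson when both margins pass Shapiro–Wilk at
    α = 0.05 and Spearman otherwise; ``"pearson"``/``"spearman"`` override.
    Constant margins make the coefficient undefined: reported as NaN with a
    warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need at least 3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant margin: correlation undefined", stacklevel=2)
        return CorrelationResult(np.nan, np.nan, "undefined")
    if force == "auto":
        px = stats.shapiro(x).pvalue
        py = stats.shapiro(y).pvalue
        method = "pearson" if (px > NORMALITY_ALPHA and py > NORMALITY_ALPHA) else "spearman"
    elif force in ("pearson", "spearman"):
        method = force
    else:
        raise ValueError(f"force must be auto|pearson|spearman, got {force!r}")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
        r, p = res.statistic, res.pvalue
    return CorrelationResult(float(r), float(p), method)


def group_assign(age: float) -> str:
    """Age-group label for an age in years on [0, 60]."""
    if not np.isfinite(age) or age < 0 or age > 60:
        raise ValueError(f"age must be within [0, 60] years, got {age}")
    for label, lo, hi in AGE_GROUP_BOUNDS[:-1]:
        closed_right = label == "18-40"
        inside = (lo <= age <= hi) if closed_right else (lo <= age < hi)
        if inside:
            return label
    return AGE_GROUP_BOUNDS[-1][0]
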