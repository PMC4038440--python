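"""Cohort-level statistics and reporting for specimen summaries.

Deliberately standard procedures — the value of this module is the
reporting shape: distribution summary tables (n, mean, median, SEM, CV,
range), normal probability plots as quantile pairs, paired-specimen
Pearson correlations with the */**/*** star convention (P ≤ 0.05/0.01/
0.001), Welch t-tests for two groups, and one-way ANOVA followed by Tukey's
studentized range test with compact letter display for multi-group
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DistributionSummary",
    "PairedCohort",
    "GroupComparison",
    "summarize_distribution",
    "normal_probability",
    "paired_correlation",
    "compare_groups",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Star convention: * P≤0.05, ** P≤0.01, *** P≤0.001, else 'ns'."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class DistributionSummary:
    """Distribution summary of one metric across a cohort."""

    n: int
    mean: float
    median: float
    sem: float
    cv: float
    min: float
    max: float

    def as_row(self) -> dict:
        return {"n": self.n, "mean": self.mean, "median": self.median,
                "sem": self.sem, "cv": self.cv, "min": self.min,
                "max": self.max}


@dataclass
class PairedCohort:
    """Paired-specimen correlation for one metric."""

    metric: str
    a: np.ndarray
    b: np.ndarray
    r: Optional[float]
    p_value: Optional[float]
    stars: str = ""
    flagged: str = ""


@dataclass
class GroupComparison:
    """Group means with letter display and the pairwise p-value table."""

    design: str                 # "two_group" or "multi_group"
    table: pd.DataFrame         # group, n, mean, sem, letters
    pairwise: pd.DataFrame      # group1, group2, p_value, significant
    p_global: Optional[float]   # ANOVA p for multi_group, t-test p for two_group


def summarize_distribution(values: np.ndarray) -> DistributionSummary:
    """n, mean, median, SEM, CV and range of a cohort metric.

    SD uses the n−1 denominator; SEM = sd/√n; CV = sd/mean.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if mean == 0 and sd > 0:
        raise ValueError("CV undefined for zero mean")
    return DistributionSummary(
        n=len(x), mean=mean, median=float(np.median(x)),
        sem=sd / np.sqrt(len(x)), cv=sd / mean if mean != 0 else 0.0,
        min=float(np.min(x)), max=float(np.max(x)))


def normal_probability(values: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Normal probability plot data: theoretical quantiles, ordered values, r².

    Plotting positions are ``(i − 0.5)/n`` mapped through the standard
    normal quantile function.  The r² of the ordered-value vs quantile OLS
    line indexes how normal the sample looks.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 values for a probability plot")
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    r2 = float(stats.linregress(q, x).rvalue ** 2)
    return q, x, r2


def paired_correlation(a: np.ndarray, b: np.ndarray,
                       metric: str = "") -> PairedCohort:
    """Pearson correlation of a paired cohort with star annotation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired sides must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return PairedCohort(metric, a, b, None, None,
                            flagged="zero variance on one side")
    r, p = stats.pearsonr(a, b)
    return PairedCohort(metric, a, b, float(r), float(p),
                        stars=significance_stars(float(p)))


def _letter_display(names: list[str], means: dict[str, float],
                    sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different.  Greedy insertion over groups sorted by descending mean."""
    order = sorted(names, key=lambda g: -means[g])
    classes: list[list[str]] = []
    for g in order:
        placed = False
        for cls in classes:
            if all(not sig[tuple(sorted((g, other)))] for other in cls):
                cls.append(g)
                placed = True
        if not placed:
            classes.append([g])
    letters = {g: "" for g in names}
    for i, cls in enumerate(classes):
        ch = chr(ord("a") + i)
        for g in cls:
            letters[g] += ch
    return letters


def compare_groups(groups: dict[str, np.ndarray],
                   design: str = "auto", alpha: float = 0.05) -> GroupComparison:
    """Two-group (Welch t) or multi-group (ANOVA + Tukey HSD) comparison.

    ``design`` may be "two_group", "multi_group" or "auto" (picked from the
    number of groups).  Means sharing a letter in the output table are not
    significantly different at ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    if design == "auto":
        design = "two_group" if len(names) == 2 else "multi_group"
    if design == "two_group" and len(names) != 2:
        raise ValueError("two_group design requires exactly 2 groups")

    sig: dict[tuple[str, str], bool] = {}
    rows = []
    if design == "two_group":
        g1, g2 = names
        t, p = stats.ttest_ind(arrays[g1], arrays[g2], equal_var=False)
        p_global = float(p)
        sig[tuple(sorted((g1, g2)))] = p_global <= alpha
        rows.append({"group1": g1, "group2": g2, "p_value": p_global,
                     "significant": p_global <= alpha})
    elif design == "multi_group":
        f, p_global = stats.f_oneway(*arrays.values())
        p_global = float(p_global)
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[g] * len(arrays[g]) for g in names])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        res = tukey.summary().data[1:]
        for row in res:
            g1, g2, _, p_adj, _, _, reject = row
            key = tuple(sorted((str(g1), str(g2))))
            sig[key] = bool(reject)
            rows.append({"group1": key[0], "group2": key[1],
                         "p_value": float(p_adj), "significant": bool(reject)})
    else:
        raise ValueError(f"unknown design {design!r}")

    means = {g: float(np.mean(v)) for g, v in arrays.items()}
    letters = _letter_display(names, means, sig)
    table = pd.DataFrame([
        {"group": g, "n": len(arrays[g]), "mean": means[g],
         "sem": float(np.std(arrays[g], ddof=1) / np.sqrt(len(arrays[g]))),
         "letters": letters[g]}
        for g in names])
    return GroupComparison(design=design, table=table,
                           pairwise=pd.DataFrame(rows), p_global=p_global)
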