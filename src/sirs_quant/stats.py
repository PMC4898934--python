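"""Group comparisons and derived ratios used in the figure-style reports.

Thin, explicit wrappers around the standard tests: pooled two-sample t,
one-way ANOVA with Bonferroni-corrected pairwise contrasts, Kruskal-Wallis,
and chi-squared on count tables (no continuity correction).  Tests are
two-sided at alpha = 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class GroupTable:
    """Labelled per-cell (or per-animal) values for one group."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"group {self.label!r} is empty")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    pairwise: list = field(default_factory=list)  # (label_a, label_b, p_corrected)


def _as_groups(groups) -> list:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupTable):
            out.append(g)
        elif isinstance(g, tuple) and len(g) == 2 and isinstance(g[0], str):
            out.append(GroupTable(label=g[0], values=g[1]))
        else:
            out.append(GroupTable(label=f"group{i}", values=g))
    return out


def compare_groups(groups, test: str = "t") -> TestResult:
    """Compare groups with t, anova, kruskal or chi2.

    For ``chi2``, ``groups`` is a 2-D count table.  Variance-based tests
    require every group to have at least 2 values.
    """
    if test == "chi2":
        table = np.asarray(groups, dtype=float)
        if table.ndim != 2:
            raise ValueError("chi2 takes a 2-D count table")
        res = sps.chi2_contingency(table, correction=False)
        return TestResult(test="chi2", statistic=float(res[0]), pvalue=float(res[1]))

    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if test in ("t", "anova") and any(g.n < 2 for g in gs):
        raise ValueError("variance-based tests need groups of size >= 2")
    values = [g.values for g in gs]

    if test == "t":
        if len(gs) != 2:
            raise ValueError("t-test takes exactly 2 groups")
        stat, p = sps.ttest_ind(values[0], values[1], equal_var=True)
        return TestResult(test="t", statistic=float(stat), pvalue=float(p))
    if test == "anova":
        stat, p = sps.f_oneway(*values)
        pairs = []
        contrasts = list(combinations(range(len(gs)), 2))
        for i, j in contrasts:
            _, pij = sps.ttest_ind(values[i], values[j], equal_var=True)
            pairs.append((gs[i].label, gs[j].label,
                          float(min(1.0, pij * len(contrasts)))))
        return TestResult(test="anova", statistic=float(stat), pvalue=float(p),
                          pairwise=pairs)
    if test == "kruskal":
        stat, p = sps.kruskal(*values)
        return TestResult(test="kruskal", statistic=float(stat), pvalue=float(p))
    raise ValueError(f"unknown test {test!r}")


def fold_change(numerator_values, denominator_values, n_boot: int = 1000,
                seed: int = 0, ci: float = 95.0):
    """mean(numerator)/mean(denominator) with a seeded bootstrap CI.

    A value of 1 means no difference between the groups.
    """
    num = np.asarray(numerator_values, dtype=float)
    den = np.asarray(denominator_values, dtype=float)
    if den.size == 0 or den.mean() <= 0:
        raise ValueError("denominator mean must be positive")
    ratio = float(num.mean() / den.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bn = num[rng.integers(0, len(num), len(num))].mean()
        bd = den[rng.integers(0, len(den), len(den))].mean()
        boots[b] = bn / bd if bd > 0 else np.nan
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.nanpercentile(boots, [alpha, 100.0 - alpha])
    return ratio, (float(lo), float(hi))


def proportion_with_event(calls) -> float:
    """Percent of divisions with any flagged anaphase error.

    ``calls`` is a list of ErrorCall-like objects (with .any_error) or
    booleans.
    """
    if len(calls) == 0:
        raise ValueError("empty call list")
    flags = [bool(getattr(c, "any_error", c)) for c in calls]
    return 100.0 * sum(flags) / len(flags)
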