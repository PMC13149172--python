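"""Group-comparison statistics for per-syncytium summary tables.

The decision tree mirrors standard applied practice for small-n
functional cohorts: normality of each group is screened with a
Kolmogorov–Smirnov-type test (Lilliefors correction, since the mean and
SD are estimated from the sample), homoscedasticity with an F-test on
the extreme (max vs min) group variances; if every premise holds at the
screening level the parametric branch runs one-way ANOVA with Tukey's
HSD for pairwise means, otherwise the nonparametric branch runs
Kruskal–Wallis with pairwise Mann–Whitney U tests at a
Bonferroni-adjusted level.  Every intermediate p-value and the branch
taken are returned so the decision is auditable.

Counts (arrhythmic vs not, per group) are compared with Pearson's
chi-square without continuity correction.  Descriptives are reported as
mean ± SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupComparison",
    "PairwiseResult",
    "compare_groups",
    "incidence_test",
    "summarize",
]


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_bonferroni: float  # Bonferroni-adjusted p (capped at 1)
    significant: bool  # at the adjusted level


@dataclass
class GroupComparison:
    """Full audit trail of one metric's group comparison."""

    metric: str
    alpha: float
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sem: dict[str, float]
    normality_p: dict[str, float]
    variance_p: float
    branch: str  # "parametric" | "nonparametric"
    omnibus_test: str  # "anova" | "kruskal"
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "alpha": self.alpha,
            "groups": {
                g: {
                    "n": self.group_n[g],
                    "mean": self.group_mean[g],
                    "sem": self.group_sem[g],
                    "normality_p": self.normality_p.get(g),
                }
                for g in self.group_n
            },
            "variance_p": self.variance_p,
            "branch": self.branch,
            "omnibus": {
                "test": self.omnibus_test,
                "statistic": self.omnibus_statistic,
                "p": self.omnibus_p,
            },
            "pairwise": [
                {
                    "a": pr.group_a,
                    "b": pr.group_b,
                    "statistic": pr.statistic,
                    "p": pr.p_value,
                    "p_bonferroni": pr.p_bonferroni,
                    "significant": pr.significant,
                }
                for pr in self.pairwise
            ],
            "notes": self.notes,
        }


def _as_group_dict(data, metric: str | None) -> dict[str, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        if metric is not None and "metric" in data.columns:
            data = data[data["metric"] == metric]
        if not {"group", "value"} <= set(data.columns):
            raise ValueError("tidy table must have columns group,value (and optionally metric)")
        return {
            str(g): sub["value"].to_numpy(dtype=float)
            for g, sub in data.groupby("group", sort=True)
        }
    return {str(g): np.asarray(v, dtype=float) for g, v in data.items()}


def compare_groups(
    data: Mapping[str, Sequence[float]] | pd.DataFrame,
    metric: str = "value",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare a metric across >= 2 groups with the premise-checked tree.

    ``data`` is either ``{group: values}`` or a tidy DataFrame with
    columns ``group``, ``value`` (and optionally ``metric`` to filter
    on).  Groups with constant values make the variance premise
    undefined; the comparison is then forced onto the nonparametric
    branch with a note.
    """
    groups = _as_group_dict(data, metric)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g in names:
        groups[g] = groups[g][np.isfinite(groups[g])]
        if groups[g].size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    notes: list[str] = []
    n_pairs = len(names) * (len(names) - 1) // 2

    # normality screening (KS with estimated parameters -> Lilliefors)
    normality_p: dict[str, float] = {}
    constant = False
    for g in names:
        vals = groups[g]
        if np.ptp(vals) == 0:
            normality_p[g] = math.nan
            constant = True
            notes.append(f"group {g!r} is constant: normality/variance tests undefined")
            continue
        if vals.size < 4:
            normality_p[g] = math.nan
            constant = True
            notes.append(f"group {g!r} too small (n={vals.size}) to screen normality")
            continue
        _, p = lilliefors(vals, dist="norm")
        normality_p[g] = float(p)

    # homoscedasticity: F-test on the extreme pair of variances,
    # Bonferroni-corrected for the number of pairwise comparisons
    if constant:
        variance_p = math.nan
    else:
        variances = {g: float(np.var(groups[g], ddof=1)) for g in names}
        g_max = max(variances, key=variances.get)
        g_min = min(variances, key=variances.get)
        if variances[g_min] == 0:
            variance_p = math.nan
            constant = True
        else:
            f = variances[g_max] / variances[g_min]
            dfn = groups[g_max].size - 1
            dfd = groups[g_min].size - 1
            tail = sps.f.sf(f, dfn, dfd)
            variance_p = float(min(1.0, 2.0 * tail * (n_pairs if len(names) > 2 else 1)))

    premises_ok = (
        not constant
        and all(p > alpha for p in normality_p.values())
        and variance_p > alpha
    )

    if premises_ok:
        branch, omnibus_test = "parametric", "anova"
        stat, p = sps.f_oneway(*(groups[g] for g in names))
        omnibus_stat, omnibus_p = float(stat), float(p)
        tukey = sps.tukey_hsd(*(groups[g] for g in names))
        pairwise = []
        for i, j in combinations(range(len(names)), 2):
            p_ij = float(tukey.pvalue[i, j])
            # Tukey already controls the family-wise rate; the Bonferroni
            # column is reported alongside without double-guessing intent.
            p_bonf = min(1.0, p_ij * n_pairs)
            pairwise.append(
                PairwiseResult(
                    group_a=names[i],
                    group_b=names[j],
                    statistic=float(tukey.statistic[i, j]),
                    p_value=p_ij,
                    p_bonferroni=p_bonf,
                    significant=p_ij < alpha,
                )
            )
    else:
        branch, omnibus_test = "nonparametric", "kruskal"
        if constant:
            notes.append("forced nonparametric branch (undefined premise test)")
        stat, p = sps.kruskal(*(groups[g] for g in names))
        omnibus_stat, omnibus_p = float(stat), float(p)
        adj_alpha = alpha / n_pairs
        pairwise = []
        for i, j in combinations(range(len(names)), 2):
            u, p_ij = sps.mannwhitneyu(groups[names[i]], groups[names[j]], alternative="two-sided")
            pairwise.append(
                PairwiseResult(
                    group_a=names[i],
                    group_b=names[j],
                    statistic=float(u),
                    p_value=float(p_ij),
                    p_bonferroni=min(1.0, float(p_ij) * n_pairs),
                    significant=float(p_ij) < adj_alpha,
                )
            )

    return GroupComparison(
        metric=metric,
        alpha=alpha,
        group_n={g: int(groups[g].size) for g in names},
        group_mean={g: float(groups[g].mean()) for g in names},
        group_sem={
            g: float(groups[g].std(ddof=1) / math.sqrt(groups[g].size)) for g in names
        },
        normality_p=normality_p,
        variance_p=variance_p,
        branch=branch,
        omnibus_test=omnibus_test,
        omnibus_statistic=omnibus_stat,
        omnibus_p=omnibus_p,
        pairwise=pairwise,
        notes=notes,
    )


def incidence_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x k incidence table (no continuity correction).

    Rows are outcome (e.g. arrhythmic / not), columns are groups.
    Returns ``(statistic, df, p)``.  Zero-margin rows or columns make
    the expected counts degenerate and raise ``ValueError``.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k contingency table with k >= 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero-margin row or column: chi-square undefined")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def summarize(data: Mapping[str, Sequence[float]] | pd.DataFrame, metric: str = "value") -> pd.DataFrame:
    """Mean ± SEM table per group (SEM is NaN for n = 1)."""
    groups = _as_group_dict(data, metric)
    rows = []
    for g in sorted(groups):
        vals = np.asarray(groups[g], dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        if n == 0:
            raise ValueError(f"group {g!r} has no values")
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
        rows.append({"group": g, "n": n, "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows)
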