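"""Shared statistical machinery used across the assay modules.

The study's testing convention for data that fail parametric assumptions is a
nonparametric cascade: a Kruskal-Wallis omnibus test across groups, followed
by all pairwise Wilcoxon rank-sum comparisons with Benjamini-Hochberg
adjustment of the pairwise p-values.  One-sample questions against a fixed
null value (e.g. arm-entry fractions against 1/3) use the Wilcoxon
signed-rank test.  Where samples are large enough for parametric analysis,
a fixed-effects linear model with ANOVA and Tukey HSD post-hoc comparisons
is used instead.

All tests are two-sided.  Rank tests use exact enumeration for small,
tie-free samples and the tie-corrected normal approximation otherwise
(scipy's automatic policy).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "bh_adjust",
    "kw_then_pairwise_wilcoxon",
    "signed_rank_vs_value",
    "anova_tukey",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``comparison`` is either a pair of group labels, or ``(group, null_value)``
    for one-sample tests.  ``p_adjusted`` is present only when the test was
    part of a jointly adjusted family.
    """

    method: str
    comparison: tuple
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        a, b = self.comparison
        return {
            "method": self.method,
            "group_a": a,
            "group_b": b,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
        }


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Flatten a list of :class:`TestResult` into a DataFrame."""
    return pd.DataFrame([r.to_row() for r in results])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order:
    ``p_adj[i] = min_{k: p_(k) >= p_(i)} ( p_(k) * n / k )`` capped at 1,
    where ``p_(k)`` is the k-th order statistic.

    Raises
    ------
    ValueError
        If the list is empty or any value is outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust requires a non-empty list of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # monotone envelope from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _split_groups(values, group):
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if values.shape != group.shape:
        raise ValueError("values and group labels must align one-to-one")
    labels = pd.unique(group)
    return {g: values[group == g] for g in labels}


def kw_then_pairwise_wilcoxon(values, group) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis omnibus followed by BH-adjusted pairwise rank-sum tests.

    Parameters
    ----------
    values, group : array-like
        Observations and their group label, aligned elementwise.

    Returns
    -------
    (omnibus, pairwise)
        The omnibus :class:`TestResult` and one :class:`TestResult` per
        unordered group pair, with ``p_adjusted`` filled in jointly across
        all pairs.
    """
    by_group = _split_groups(values, group)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    h, p = stats.kruskal(*by_group.values())
    omnibus = TestResult(
        method="kruskal-wallis",
        comparison=("all", tuple(by_group)),
        statistic=float(h),
        p_value=float(p),
    )

    pairwise: list[TestResult] = []
    for a, b in itertools.combinations(by_group, 2):
        u, pw = stats.mannwhitneyu(
            by_group[a], by_group[b], alternative="two-sided", method="auto"
        )
        pairwise.append(
            TestResult(
                method="wilcoxon-rank-sum",
                comparison=(a, b),
                statistic=float(u),
                p_value=float(pw),
            )
        )
    adj = bh_adjust([r.p_value for r in pairwise])
    for r, pa in zip(pairwise, adj):
        r.p_adjusted = float(pa)
    return omnibus, pairwise


def signed_rank_vs_value(values, null_value: float) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against a fixed value.

    Observations equal to ``null_value`` are discarded (the classic
    signed-rank convention); if none remain the test is undefined.
    """
    v = np.asarray(values, dtype=float)
    d = v - null_value
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all observations equal the null value; test undefined")
    stat, p = stats.wilcoxon(d, alternative="two-sided", method="auto")
    return TestResult(
        method="wilcoxon-signed-rank",
        comparison=("sample", null_value),
        statistic=float(stat),
        p_value=float(p),
        extra={"n_used": int(d.size)},
    )


def anova_tukey(
    df: pd.DataFrame,
    value: str,
    group: str,
    block: str | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed-effects linear model ANOVA with Tukey HSD post-hoc comparisons.

    ``block`` (e.g. a biological replicate) is included as an additional fixed
    effect when given.  This is the parametric path used for large pooled
    samples (alternation scores, nuclear ratios, cell counts); it delegates
    to statsmodels.

    Returns the ANOVA table and the Tukey HSD summary as DataFrames.
    """
    data = df[[value, group] + ([block] if block else [])].dropna().copy()
    rhs = f"C({group})" + (f" + C({block})" if block else "")
    model = ols(f"{value} ~ {rhs}", data=data).fit()
    table = anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(data[value], data[group], alpha=alpha)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return table, tukey_df
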