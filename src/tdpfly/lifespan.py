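"""Kaplan-Meier lifespan analysis.

Survival of aging cohorts is censused every other day up to a 100-day
horizon, so event times live on a 2-day grid and ties are common.  The
product-limit estimator, Greenwood variance, log-log pointwise confidence
band, median survival with its Brookmeyer-Crowley style CI (the band
intersected with 0.5), and the log-rank test are exposed here; estimation
delegates to lifelines.  At tied times deaths precede censorings (the
standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import median_survival_times

from .statcore import TestResult

__all__ = [
    "SurvivalCurve",
    "km_estimate",
    "median_with_ci",
    "logrank",
    "fit_by_group",
]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate for one cohort.

    ``survival`` is the step function S(t) evaluated at ``timeline``;
    ``greenwood_var`` is the Greenwood variance of S(t); the CI columns come
    from the log-log (exponential Greenwood) transform, which respects the
    [0, 1] bounds.  ``median`` is the smallest t with S(t) <= 0.5, NaN when
    S never reaches 0.5.
    """

    label: str
    timeline: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    greenwood_var: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int
    event_table: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.timeline,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "greenwood_var": self.greenwood_var,
            }
        )


def _greenwood(event_table: pd.DataFrame, survival: pd.Series) -> np.ndarray:
    d = event_table["observed"].to_numpy(float)
    n = event_table["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > d, d / (n * (n - d)), np.nan)
    cum = np.nancumsum(term)
    return survival.to_numpy() ** 2 * cum


def km_estimate(
    time_days, event, label: str = "cohort", alpha: float = 0.05
) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood SE and log-log CI.

    Parameters
    ----------
    time_days : array-like
        Death or censoring time per fly (must be > 0).
    event : array-like of bool/int
        1 if the fly died at that time, 0 if right-censored.
    """
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event).astype(bool)
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    if e.sum() == 0 and t.size == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, event_observed=e, label=label)
    surv = kmf.survival_function_[label]
    ci = kmf.confidence_interval_
    med = kmf.median_survival_time_
    med_ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
    return SurvivalCurve(
        label=label,
        timeline=surv.index.to_numpy(float),
        survival=surv.to_numpy(float),
        ci_lower=ci.iloc[:, 0].to_numpy(float),
        ci_upper=ci.iloc[:, 1].to_numpy(float),
        greenwood_var=_greenwood(kmf.event_table, surv),
        median=float(med),
        median_ci=(lo, hi),
        n=int(t.size),
        n_events=int(e.sum()),
        event_table=kmf.event_table,
    )


def median_with_ci(curve: SurvivalCurve) -> tuple[float, float, float]:
    """(median, lower, upper); median/bounds are inf when S never crosses 0.5."""
    return (curve.median, *curve.median_ci)


def logrank(time_days, event, group) -> TestResult:
    """Log-rank test across genotype groups (chi-square for k > 2)."""
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event).astype(int)
    g = np.asarray(group)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    if len(labels) == 2:
        a, b = labels
        res = logrank_test(t[g == a], t[g == b], e[g == a], e[g == b])
        comparison = (a, b)
    else:
        res = multivariate_logrank_test(t, g, e)
        comparison = ("all", tuple(labels))
    return TestResult(
        method="log-rank",
        comparison=comparison,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def fit_by_group(
    records: pd.DataFrame,
    time_col: str = "time_days",
    event_col: str = "event",
    by: str = "genotype",
) -> tuple[dict[str, SurvivalCurve], TestResult | None]:
    """Per-group KM curves plus the across-group log-rank test.

    ``event`` may be coded 0/1 or as the strings died/censored.  Sexes are
    pooled (the study pools them for lifespan).
    """
    df = records.copy()
    if df[event_col].dtype == object:
        df[event_col] = (df[event_col] == "died").astype(int)
    curves = {
        str(gname): km_estimate(sub[time_col], sub[event_col], label=str(gname))
        for gname, sub in df.groupby(by)
    }
    test = None
    if df[by].nunique() >= 2:
        test = logrank(df[time_col], df[event_col], df[by])
    return curves, test
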