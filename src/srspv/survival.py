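"""Kaplan–Meier onset curves and the two-arm log-rank comparison.

In spontaneous-report data every retained record experienced the event
(there is no at-risk cohort), so all observations are events and the
product-limit estimate coincides with 1 − ECDF.  The censoring-capable
machinery (lifelines) is used anyway for generality; a censoring flag
is accepted but defaults to all-events.

The two-arm contrast (e.g. solvent-based vs albumin-bound paclitaxel)
uses the Mantel–Cox log-rank test with the standard hypergeometric
variance and ties pooled at shared event times; significance is read at
P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .time_to_onset import DEFAULT_WINDOW_DAYS, MIN_FIT_N, LatencySet, compute_latencies, summarize_latency

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class KMCurve:
    """Product-limit estimate as a step function."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival_probs = np.asarray(self.survival_probs, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if not (len(self.event_times) == len(self.survival_probs) == len(self.n_at_risk)):
            raise ValueError("inconsistent KM curve lengths")
        if np.any(np.diff(self.survival_probs) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.event_times,
                "survival": self.survival_probs,
                "n_at_risk": self.n_at_risk,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    degrees_freedom: int
    p_value: float

    def __post_init__(self) -> None:
        if self.chi_square < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ValueError("invalid log-rank result")


@dataclass
class OnsetComparisonResults:
    """Bundle of the two-arm onset comparison."""

    label1: str
    label2: str
    curve1: KMCurve
    curve2: KMCurve
    logrank: LogRankResult
    median1_days: Optional[float]
    median2_days: Optional[float]
    n1: int
    n2: int
    significant: bool
    warnings: list[str]

    def summary(self) -> str:
        lines = [
            f"Onset comparison: {self.label1} (n={self.n1}) vs {self.label2} (n={self.n2})",
            f"  median {self.label1}: {self.median1_days} days; "
            f"median {self.label2}: {self.median2_days} days",
            f"  log-rank chi2={self.logrank.chi_square:.3f}, df={self.logrank.degrees_freedom}, "
            f"P={self.logrank.p_value:.4g} "
            f"({'significant' if self.significant else 'not significant'} at P<{SIGNIFICANCE_LEVEL})",
        ]
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def km_estimate(
    latencies: LatencySet | Sequence[float],
    event_observed: Optional[Sequence[int]] = None,
) -> KMCurve:
    """Product-limit estimate; with no censoring this equals 1 − ECDF."""
    values = (
        latencies.latencies_days if isinstance(latencies, LatencySet) else np.asarray(latencies, float)
    )
    if len(values) == 0:
        raise ValueError("empty latency set")
    kmf = KaplanMeierFitter()
    kmf.fit(values, event_observed=event_observed)
    table = kmf.event_table[kmf.event_table["observed"] > 0]  # drop the t=0 anchor
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times].iloc[:, 0].to_numpy()
    return KMCurve(
        event_times=times,
        survival_probs=surv,
        n_at_risk=table["at_risk"].to_numpy(),
    )


class OnsetComparison:
    """Two-arm time-to-onset comparison model.

    Construct from two latency sets (or directly from analysis records
    via :func:`compare_onset_profiles`); ``fit()`` returns an
    :class:`OnsetComparisonResults` with both KM curves, the Mantel–Cox
    log-rank test, and the arm medians.
    """

    def __init__(self, group1: LatencySet, group2: LatencySet) -> None:
        if group1.n == 0 or group2.n == 0:
            raise ValueError("both comparison arms must be non-empty")
        self.group1 = group1
        self.group2 = group2

    def fit(self) -> OnsetComparisonResults:
        g1, g2 = self.group1, self.group2
        res = _lifelines_logrank(g1.latencies_days, g2.latencies_days)
        logrank = LogRankResult(
            chi_square=float(res.test_statistic),
            degrees_freedom=1,
            p_value=float(res.p_value),
        )
        warnings = [
            f"{g.drug_or_class}: n={g.n} below {MIN_FIT_N}; comparison is descriptive"
            for g in (g1, g2)
            if g.n < MIN_FIT_N
        ]
        return OnsetComparisonResults(
            label1=g1.drug_or_class,
            label2=g2.drug_or_class,
            curve1=km_estimate(g1),
            curve2=km_estimate(g2),
            logrank=logrank,
            median1_days=summarize_latency(g1).median_days,
            median2_days=summarize_latency(g2).median_days,
            n1=g1.n,
            n2=g2.n,
            significant=logrank.p_value < SIGNIFICANCE_LEVEL,
            warnings=warnings,
        )


def logrank_test(group1: LatencySet | Sequence[float], group2: LatencySet | Sequence[float]) -> LogRankResult:
    """Mantel–Cox log-rank test between two uncensored latency samples."""
    x1 = group1.latencies_days if isinstance(group1, LatencySet) else np.asarray(group1, float)
    x2 = group2.latencies_days if isinstance(group2, LatencySet) else np.asarray(group2, float)
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(x1, x2)
    return LogRankResult(
        chi_square=float(res.test_statistic), degrees_freedom=1, p_value=float(res.p_value)
    )


def compare_onset_profiles(
    records: pd.DataFrame,
    drug1: str,
    drug2: str,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> OnsetComparisonResults:
    """End-to-end two-drug onset comparison from analysis records."""
    lat1 = compute_latencies(records, drug1, window_days)
    lat2 = compute_latencies(records, drug2, window_days)
    return OnsetComparison(lat1, lat2).fit()
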