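"""Time-to-onset latencies and Weibull hazard classification.

For each (report, drug) analysis record with complete dates, the
latency is the number of days from the earliest administration start
to the first onset of the focal event.  Following standard
spontaneous-report practice, records are excluded (and counted) when

* either date is incomplete (year-month or year precision),
* the latency is negative (onset before administration), or
* the latency exceeds the analysis window (365 days by default).

The retained latencies are summarised by median and quartiles (the
(n+1)p convention with linear interpolation, matching common
statistical software) and fitted with a two-parameter Weibull
distribution

    f(t) = (β/α) (t/α)^{β−1} exp(−(t/α)^β),   t > 0,

whose shape parameter β indexes how the reporting hazard changes with
time since administration: a 95% CI for β entirely below 1 indicates a
decreasing hazard ("initial failure" — onsets concentrate early),
entirely above 1 an increasing hazard ("wear-out failure"), and a CI
spanning 1 a constant hazard ("random failure").

Estimation is by maximum likelihood on (log α, log β) with Wald
confidence intervals from the observed information at the optimum.
Zero-day latencies (same-day onset) are shifted to 0.5 days for the fit
only — the log-density is undefined at 0 — and kept at 0 for the
median/quartile summaries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dates import days_between, parse_partial_date

DEFAULT_WINDOW_DAYS = 365
MIN_FIT_N = 10  # classes with fewer retained latencies are not fitted
ZERO_LATENCY_SHIFT = 0.5


class HazardClass(str, enum.Enum):
    INITIAL_FAILURE = "initial_failure"  # hazard decreases over time
    RANDOM_FAILURE = "random_failure"  # hazard roughly constant
    WEAR_OUT_FAILURE = "wear_out_failure"  # hazard increases over time


class FitError(RuntimeError):
    """Weibull maximum-likelihood estimation failed to converge."""


@dataclass
class LatencySet:
    """Retained per-report latencies plus full exclusion accounting."""

    drug_or_class: str
    latencies_days: np.ndarray
    n_excluded_incomplete: int = 0
    n_excluded_negative: int = 0
    n_excluded_window: int = 0
    n_excluded_duplicate: int = 0
    window_days: int = DEFAULT_WINDOW_DAYS

    def __post_init__(self) -> None:
        self.latencies_days = np.asarray(self.latencies_days, dtype=float)
        if len(self.latencies_days):
            if self.latencies_days.min() < 0:
                raise ValueError("negative latency retained")
            if self.latencies_days.max() > self.window_days:
                raise ValueError("latency beyond the analysis window retained")

    @property
    def n(self) -> int:
        return len(self.latencies_days)


@dataclass(frozen=True)
class LatencySummary:
    median_days: float
    q1_days: float
    q3_days: float
    n: int


@dataclass
class WeibullFit:
    """MLE of the Weibull time-to-onset distribution for one drug/class."""

    drug_or_class: str
    alpha_days: float
    alpha_ci: tuple[float, float]
    beta: float
    beta_ci: tuple[float, float]
    log_likelihood: float
    n: int
    hazard_class: HazardClass = field(init=False)

    def __post_init__(self) -> None:
        self.hazard_class = classify_hazard(self)

    def summary(self) -> str:
        a, (al, ah) = self.alpha_days, self.alpha_ci
        b, (bl, bh) = self.beta, self.beta_ci
        return (
            f"{self.drug_or_class}: n={self.n}, "
            f"alpha={a:.2f} ({al:.2f}-{ah:.2f}) days, "
            f"beta={b:.2f} ({bl:.2f}-{bh:.2f}), {self.hazard_class.value}"
        )


def compute_latencies(
    records: pd.DataFrame,
    drug_or_class: str,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> LatencySet:
    """Derive the latency set for one drug/class from analysis records.

    Only case records (focal event present) are candidates.  Duplicate
    prescriptions were collapsed upstream; the number of collapsed rows
    is surfaced in ``n_excluded_duplicate``.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    rows = records[(records["drug"] == drug_or_class) & records["is_case"]]
    latencies = []
    n_incomplete = n_negative = n_window = 0
    n_duplicate = int((rows["n_prescription_rows"] - 1).clip(lower=0).sum())
    for start_text, onset_text in zip(rows["start_date"], rows["onset_date"]):
        start = parse_partial_date(start_text)
        onset = parse_partial_date(onset_text)
        if start is None or onset is None or not (start.is_full and onset.is_full):
            n_incomplete += 1
            continue
        delta = days_between(start, onset)
        if delta < 0:
            n_negative += 1
        elif delta > window_days:
            n_window += 1
        else:
            latencies.append(float(delta))
    return LatencySet(
        drug_or_class=drug_or_class,
        latencies_days=np.array(latencies),
        n_excluded_incomplete=n_incomplete,
        n_excluded_negative=n_negative,
        n_excluded_window=n_window,
        n_excluded_duplicate=n_duplicate,
        window_days=window_days,
    )


def summarize_latency(latencies: LatencySet, method: str = "weibull") -> LatencySummary:
    """Median and quartiles of the retained latencies.

    ``method`` is a numpy quantile method name; the default ``weibull``
    is the (n+1)p plotting-position convention with linear
    interpolation.
    """
    x = latencies.latencies_days
    if len(x) == 0:
        raise ValueError(f"no retained latencies for {latencies.drug_or_class!r}")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=method)
    return LatencySummary(median_days=float(med), q1_days=float(q1), q3_days=float(q3), n=len(x))


def _negative_log_likelihood(theta: np.ndarray, t: np.ndarray, log_t: np.ndarray) -> float:
    log_alpha, log_beta = theta
    beta = math.exp(log_beta)
    z = (log_t - log_alpha) * beta  # log((t/alpha)^beta)
    if z.max() > 700.0:  # overflow guard; such points are hopeless anyway
        return np.inf
    return float(-(len(t) * log_beta - len(t) * beta * log_alpha
                   + (beta - 1.0) * log_t.sum() - np.exp(z).sum()))


def _hessian(theta: np.ndarray, t: np.ndarray, log_t: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Observed information: central finite differences of the NLL."""
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            hess[i, j] = (
                _negative_log_likelihood(theta + ei + ej, t, log_t)
                - _negative_log_likelihood(theta + ei - ej, t, log_t)
                - _negative_log_likelihood(theta - ei + ej, t, log_t)
                + _negative_log_likelihood(theta - ei - ej, t, log_t)
            ) / (4.0 * h * h)
    return hess


class WeibullTimeToOnset:
    """Weibull time-to-onset model for one set of latencies.

    Statsmodels-style: construct from data, call :meth:`fit` to obtain a
    :class:`WeibullFit` results object.

    Parameters
    ----------
    latencies
        A :class:`LatencySet` or plain sequence of latencies in days.
        Values must be non-negative; zeros are shifted to 0.5 days for
        the likelihood.
    min_n
        Refuse to fit below this sample size (default 10, matching the
        practice of analysing only classes with enough reports).
    """

    def __init__(
        self,
        latencies: LatencySet | Sequence[float],
        label: Optional[str] = None,
        min_n: int = MIN_FIT_N,
    ) -> None:
        if isinstance(latencies, LatencySet):
            self.label = label if label is not None else latencies.drug_or_class
            values = latencies.latencies_days
        else:
            self.label = label or ""
            values = np.asarray(latencies, dtype=float)
        if len(values) and values.min() < 0:
            raise ValueError("latencies must be non-negative")
        self.raw = values
        self.min_n = min_n

    def fit(self, ci_level: float = 0.95) -> WeibullFit:
        t = np.where(self.raw <= 0.0, ZERO_LATENCY_SHIFT, self.raw)
        n = len(t)
        if n < self.min_n:
            raise FitError(
                f"{self.label or 'latency set'}: n={n} below the minimum of {self.min_n}"
            )
        log_t = np.log(t)

        # moment-style start: beta from the coefficient of variation,
        # alpha from the mean
        mean, sd = float(t.mean()), float(t.std(ddof=1))
        cv = sd / mean if mean > 0 and sd > 0 else 1.0
        beta0 = min(max(cv ** -1.086, 0.05), 50.0)
        alpha0 = mean / special.gamma(1.0 + 1.0 / beta0)
        starts = [np.array([math.log(alpha0), math.log(beta0)])]
        # fallback multi-start grid around the exponential case
        for b in (0.5, 1.0, 2.0):
            starts.append(np.array([math.log(mean), math.log(b)]))

        best = None
        for theta0 in starts:
            res = optimize.minimize(
                _negative_log_likelihood, theta0, args=(t, log_t),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitError(f"{self.label or 'latency set'}: Weibull MLE did not converge")

        theta = best.x
        hess = _hessian(theta, t, log_t)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"{self.label}: singular observed information") from exc
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        alpha_hat, beta_hat = math.exp(theta[0]), math.exp(theta[1])
        return WeibullFit(
            drug_or_class=self.label,
            alpha_days=alpha_hat,
            alpha_ci=(math.exp(theta[0] - z * se[0]), math.exp(theta[0] + z * se[0])),
            beta=beta_hat,
            beta_ci=(math.exp(theta[1] - z * se[1]), math.exp(theta[1] + z * se[1])),
            log_likelihood=-float(best.fun),
            n=n,
        )


def fit_weibull(latencies: LatencySet | Sequence[float], ci_level: float = 0.95) -> WeibullFit:
    """Functional wrapper over :class:`WeibullTimeToOnset`."""
    return WeibullTimeToOnset(latencies).fit(ci_level)


def classify_hazard(fit: "WeibullFit | tuple[float, float]") -> HazardClass:
    """Hazard class from the β CI; the boundary value 1 is 'random'.

    Strict inequalities: initial failure iff the CI upper bound < 1,
    wear-out iff the lower bound > 1, otherwise random failure.
    """
    low, high = fit if isinstance(fit, tuple) else fit.beta_ci
    if high < 1.0:
        return HazardClass.INITIAL_FAILURE
    if low > 1.0:
        return HazardClass.WEAR_OUT_FAILURE
    return HazardClass.RANDOM_FAILURE


def tto_table(
    records: pd.DataFrame,
    targets: Sequence[str],
    window_days: int = DEFAULT_WINDOW_DAYS,
    ci_level: float = 0.95,
    min_n: int = MIN_FIT_N,
) -> pd.DataFrame:
    """Median/IQR + Weibull outputs for a list of drugs/classes.

    Targets with too few retained latencies keep their summary row but
    have empty Weibull columns.
    """
    rows = []
    for target in targets:
        lat = compute_latencies(records, target, window_days)
        row = {
            "drug_or_class": target,
            "n": lat.n,
            "n_excluded_incomplete": lat.n_excluded_incomplete,
            "n_excluded_negative": lat.n_excluded_negative,
            "n_excluded_window": lat.n_excluded_window,
            "n_excluded_duplicate": lat.n_excluded_duplicate,
        }
        if lat.n >= 1:
            summ = summarize_latency(lat)
            row.update(median_days=summ.median_days, q1_days=summ.q1_days, q3_days=summ.q3_days)
        if lat.n >= min_n:
            try:
                fit = WeibullTimeToOnset(lat, min_n=min_n).fit(ci_level)
                row.update(
                    alpha=fit.alpha_days,
                    alpha_ci_low=fit.alpha_ci[0],
                    alpha_ci_high=fit.alpha_ci[1],
                    beta=fit.beta,
                    beta_ci_low=fit.beta_ci[0],
                    beta_ci_high=fit.beta_ci[1],
                    hazard_class=fit.hazard_class.value,
                )
            except FitError:
                row["hazard_class"] = "fit_failed"
        rows.append(row)
    return pd.DataFrame(rows)
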