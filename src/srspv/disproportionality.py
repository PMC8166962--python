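"""Reporting odds ratio (ROR) signal detection on 2×2 report tables.

The ROR is the standard disproportionality statistic for spontaneous
reporting systems.  For one drug (or ATC class) and one adverse event,
reports are cross-classified as

    =============  =========  ============
    .              event      other events
    =============  =========  ============
    drug           a          b
    other drugs    c          d
    =============  =========  ============

and ROR = (a·d)/(b·c), the odds of the event being reported under the
drug relative to the rest of the database.  The 95% confidence interval
is the Woolf (logit) interval,

    exp( ln ROR ± z · sqrt(1/a + 1/b + 1/c + 1/d) ),

and a *signal* is declared when ROR > 1, the CI lower bound exceeds 1,
and at least two case reports exist.  The ROR indexes reporting
disproportion, not absolute risk, and carries no causal weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from ._util import round_half_up

MIN_CASES_FOR_SIGNAL = 2


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the drug × event 2×2 report table.

    Cells are counts in observed tables; the synthetic-data oracle uses
    real-valued expected cells (``validate_integers=False``).
    """

    a: float  # drug & event
    b: float  # drug, no event
    c: float  # no drug, event
    d: float  # neither
    validate_integers: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in 2x2 table: {cells}")
        if self.validate_integers and any(x != int(x) for x in cells):
            raise ValueError(f"non-integer counts in 2x2 table: {cells}")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        """Cross-product ratio; inf/nan when cells are zero."""
        if self.b == 0 or self.c == 0:
            return math.inf if self.a > 0 and self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)

    def haldane_corrected(self) -> "ContingencyTable":
        """Add 0.5 to every cell (Haldane–Anscombe); non-default mode."""
        return ContingencyTable(
            self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5,
            validate_integers=False,
        )


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate, Woolf CI, and the signal decision for one target."""

    drug_or_class: str
    n_case: int
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    evaluable: bool
    is_signal: bool = False
    table: Optional[ContingencyTable] = None

    def rounded(self, digits: int = 1) -> tuple:
        """Presentation values: one-decimal, round-half-up convention."""
        if not self.evaluable:
            return (None, None, None)
        return (
            round_half_up(self.ror, digits),
            round_half_up(self.ci_low, digits),
            round_half_up(self.ci_high, digits),
        )

    def summary(self) -> str:
        if not self.evaluable:
            return f"{self.drug_or_class}: n_case={self.n_case}, not evaluable"
        r, lo, hi = self.rounded()
        star = " *" if self.is_signal else ""
        return f"{self.drug_or_class}: n_case={self.n_case}, ROR {r} ({lo}–{hi}){star}"


class ReportingOddsRatio:
    """Disproportionality model for one 2×2 report table.

    Parameters
    ----------
    table
        The a/b/c/d report counts.
    label
        Name of the drug or ATC class (carried into the results).
    zero_cell_correction
        If true, apply the Haldane–Anscombe 0.5 correction before
        estimating.  Off by default: tables with empty cells are
        reported as non-evaluable rather than corrected.

    ``fit(ci_level)`` returns a :class:`SignalResult`.
    """

    def __init__(
        self,
        table: ContingencyTable,
        label: str = "",
        zero_cell_correction: bool = False,
    ) -> None:
        self.table = table
        self.label = label
        self.zero_cell_correction = zero_cell_correction

    def fit(self, ci_level: float = 0.95) -> SignalResult:
        if not 0.0 < ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        raw = self.table
        table = raw.haldane_corrected() if self.zero_cell_correction else raw
        n_case = int(raw.a)
        evaluable = (
            n_case >= MIN_CASES_FOR_SIGNAL
            and table.b > 0
            and table.c > 0
            and table.d > 0
        )
        if not evaluable:
            return SignalResult(
                drug_or_class=self.label, n_case=n_case,
                ror=None, ci_low=None, ci_high=None,
                evaluable=False, table=raw,
            )
        ror = table.odds_ratio()
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        se = math.sqrt(1.0 / table.a + 1.0 / table.b + 1.0 / table.c + 1.0 / table.d)
        log_ror = math.log(ror)
        result = SignalResult(
            drug_or_class=self.label, n_case=n_case,
            ror=ror,
            ci_low=math.exp(log_ror - z * se),
            ci_high=math.exp(log_ror + z * se),
            evaluable=True, table=raw,
        )
        return detect_signal(result)


def build_contingency(
    records: pd.DataFrame,
    drug_or_class: str,
    total_reports: int,
    total_cases: int,
) -> ContingencyTable:
    """Assemble the 2×2 table for one drug/class from analysis records.

    ``records`` is the per-(report, drug) analysis set; exposure is
    report-level (a report exposed through several rows counts once).
    ``total_reports`` and ``total_cases`` are whole-database denominators.
    """
    if total_cases > total_reports:
        raise ValueError("total_cases exceeds total_reports")
    mask = records["drug"] == drug_or_class
    exposed = records.loc[mask]
    exposed_ids = exposed.drop_duplicates(subset="case_id")
    a = int(exposed_ids["is_case"].sum())
    b = int(len(exposed_ids) - a)
    c = total_cases - a
    d = total_reports - a - b - c
    if c < 0 or d < 0:
        raise ValueError(
            f"inconsistent denominators for {drug_or_class!r}: a={a} b={b} c={c} d={d}"
        )
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_ror(
    table: ContingencyTable,
    ci_level: float = 0.95,
    label: str = "",
    zero_cell_correction: bool = False,
) -> SignalResult:
    """ROR with Woolf CI; undefined tables yield a non-evaluable result."""
    return ReportingOddsRatio(table, label, zero_cell_correction).fit(ci_level)


def detect_signal(result: SignalResult) -> SignalResult:
    """Apply the signal rule: ROR > 1, CI lower bound > 1, ≥ 2 cases."""
    is_signal = bool(
        result.evaluable
        and result.ror is not None
        and result.ror > 1.0
        and result.ci_low > 1.0
        and result.n_case >= MIN_CASES_FOR_SIGNAL
    )
    return replace(result, is_signal=is_signal)


def run_signal_screen(
    records: pd.DataFrame,
    targets: Sequence[str],
    total_reports: int,
    total_cases: int,
    ci_level: float = 0.95,
    zero_cell_correction: bool = False,
) -> pd.DataFrame:
    """Screen a list of drugs/classes; one row per target.

    Denominators are recomputed by the caller from the dataset itself
    (``n_reports`` and the flagged-case count), never trusted from
    configuration.  Output rows are ordered by ATC code then name when
    an ``atc_code`` column is present, else by name.
    """
    if not len(targets):
        raise ValueError("no screen targets given")
    rows = []
    known = set(records["drug"])
    atc_by_drug = (
        records.drop_duplicates("drug").set_index("drug")["atc_code"].to_dict()
        if "atc_code" in records.columns
        else {}
    )
    for target in targets:
        if target in known:
            table = build_contingency(records, target, total_reports, total_cases)
            res = compute_ror(table, ci_level, target, zero_cell_correction)
            total_n = int(table.a + table.b)
        else:
            res = SignalResult(target, 0, None, None, None, evaluable=False)
            total_n = 0
        ror, lo, hi = res.rounded()
        rows.append(
            {
                "atc_code": atc_by_drug.get(target, ""),
                "drug_or_class": target,
                "total_n": total_n,
                "n_case": res.n_case,
                "ror": res.ror,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ror_1dp": ror,
                "ci_low_1dp": lo,
                "ci_high_1dp": hi,
                "is_signal": res.is_signal,
                "evaluable": res.evaluable,
                "total_reports": total_reports,
                "total_cases": total_cases,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["atc_code", "drug_or_class"], kind="stable").reset_index(drop=True)
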