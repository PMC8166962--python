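"""Outcome profiles of the focal event per drug or ATC class.

Reported outcomes fall into six categories — death, with sequelae, not
recovered, improved, recovered, unknown — plus blanks.  "Unknown" and
blank outcomes are excluded (and counted), leaving a five-category
denominator per drug/class.  The combined *unfavourable* fraction pools
death + with sequelae + not recovered; *favourable* pools recovered +
improved; the two sum to one by construction.

``mosaic_data`` emits the rectangle geometry of the classic mosaic
plot: column widths proportional to the per-class denominators and
vertical segments proportional to category shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from ._util import round_half_up

RETAINED_CATEGORIES = ("death", "with_sequelae", "not_recovered", "improved", "recovered")
UNFAVOURABLE = ("death", "with_sequelae", "not_recovered")
FAVOURABLE = ("recovered", "improved")


@dataclass
class OutcomeTable:
    """Per-category case counts for one drug/class, unknowns excluded."""

    drug_or_class: str
    counts: dict[str, int]
    n_excluded_unknown: int = 0

    def __post_init__(self) -> None:
        self.counts = {cat: int(self.counts.get(cat, 0)) for cat in RETAINED_CATEGORIES}
        if any(v < 0 for v in self.counts.values()) or self.n_excluded_unknown < 0:
            raise ValueError("negative outcome count")

    @property
    def denominator(self) -> int:
        return sum(self.counts.values())


def tabulate_outcomes(records: pd.DataFrame, drug_or_class: str) -> OutcomeTable:
    """Count outcome categories over the case records of one drug/class."""
    rows = records[(records["drug"] == drug_or_class) & records["is_case"]]
    counts = {cat: 0 for cat in RETAINED_CATEGORIES}
    n_excluded = 0
    for outcome in rows["outcome"]:
        if outcome in counts:
            counts[outcome] += 1
        else:  # unknown or blank
            n_excluded += 1
    return OutcomeTable(drug_or_class=drug_or_class, counts=counts, n_excluded_unknown=n_excluded)


def combined_frequencies(table: OutcomeTable) -> tuple[float, float]:
    """(favourable, unfavourable) fractions; exact complements.

    Computed in rational arithmetic so the pair sums to 1 exactly
    before any presentation rounding.
    """
    denom = table.denominator
    if denom < 1:
        raise ValueError(f"{table.drug_or_class!r}: outcome denominator is zero")
    unfav = Fraction(sum(table.counts[c] for c in UNFAVOURABLE), denom)
    fav = 1 - unfav
    return float(fav), float(unfav)


def outcome_percentages(table: OutcomeTable, digits: int = 1) -> dict[str, float]:
    """Per-category percentages with round-half-up presentation."""
    denom = table.denominator
    if denom < 1:
        raise ValueError(f"{table.drug_or_class!r}: outcome denominator is zero")
    return {
        cat: round_half_up(100.0 * n / denom, digits) for cat, n in table.counts.items()
    }


def mosaic_data(tables: Sequence[OutcomeTable]) -> pd.DataFrame:
    """Rectangle proportions for a mosaic plot of outcomes by class.

    One row per (class, category): ``column_width`` is the class share
    of the pooled denominator, ``segment_height`` the category share
    within the class (columns with a zero denominator get zero-height
    segments); heights sum to 1 per non-empty column.
    """
    if not tables:
        raise ValueError("mosaic_data needs at least one outcome table")
    total = sum(t.denominator for t in tables)
    rows = []
    for t in tables:
        width = t.denominator / total if total else 0.0
        for cat in RETAINED_CATEGORIES:
            rows.append(
                {
                    "drug_or_class": t.drug_or_class,
                    "category": cat,
                    "count": t.counts[cat],
                    "column_width": width,
                    "segment_height": (t.counts[cat] / t.denominator) if t.denominator else 0.0,
                }
            )
    return pd.DataFrame(rows)


def outcome_screen(records: pd.DataFrame, targets: Sequence[str]) -> pd.DataFrame:
    """Outcome table + combined fractions for a list of drugs/classes."""
    rows = []
    for target in targets:
        table = tabulate_outcomes(records, target)
        row = {"drug_or_class": target, **table.counts,
               "n_excluded_unknown": table.n_excluded_unknown,
               "denominator": table.denominator}
        if table.denominator >= 1:
            fav, unfav = combined_frequencies(table)
            row["favourable_pct"] = round_half_up(100.0 * fav, 1)
            row["unfavourable_pct"] = round_half_up(100.0 * unfav, 1)
        rows.append(row)
    return pd.DataFrame(rows)
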