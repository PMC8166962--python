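"""Partial calendar dates as they occur in spontaneous-report databases.

Report databases record administration and onset dates with varying
precision: a full day, a year-month, or a bare year.  Time-to-onset
analysis needs day-level arithmetic and must *exclude* (never impute)
records whose dates are not complete, so completeness is carried
explicitly and a partial date can never silently act as a full one.

The serialised dialect is a plain digit string: ``YYYYMMDD``, ``YYYYMM``
or ``YYYY``.  An empty string denotes an absent date.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from typing import Optional


class Completeness(str, enum.Enum):
    FULL = "full"
    YEAR_MONTH = "year_month"
    YEAR_ONLY = "year_only"


class DateParseError(ValueError):
    """Raised when a string is not a valid (partial) date."""


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date known to full, year-month, or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.year <= 9999:
            raise DateParseError(f"year out of range: {self.year}")
        if self.day is not None and self.month is None:
            raise DateParseError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise DateParseError(f"month out of range: {self.month}")
        if self.day is not None:
            try:  # delegates leap years / month lengths to datetime
                _dt.date(self.year, self.month, self.day)
            except ValueError as exc:
                raise DateParseError(
                    f"invalid calendar date {self.year:04d}-{self.month:02d}-{self.day:02d}"
                ) from exc

    @property
    def completeness(self) -> Completeness:
        if self.day is not None:
            return Completeness.FULL
        if self.month is not None:
            return Completeness.YEAR_MONTH
        return Completeness.YEAR_ONLY

    @property
    def is_full(self) -> bool:
        return self.day is not None

    def to_ordinal(self) -> int:
        """Proleptic-Gregorian ordinal day number; full dates only."""
        if not self.is_full:
            raise ValueError(f"partial date {self} has no ordinal day number")
        return _dt.date(self.year, self.month, self.day).toordinal()

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(text: str) -> Optional[PartialDate]:
    """Parse a digit-string date; '' → None (absent).

    Accepted layouts: 8 digits (YYYYMMDD), 6 digits (YYYYMM),
    4 digits (YYYY).  Anything else raises :class:`DateParseError`.
    """
    text = text.strip()
    if text == "":
        return None
    if not text.isdigit() or len(text) not in (4, 6, 8):
        raise DateParseError(f"not a YYYY[MM[DD]] digit string: {text!r}")
    year = int(text[:4])
    month = int(text[4:6]) if len(text) >= 6 else None
    day = int(text[6:8]) if len(text) == 8 else None
    return PartialDate(year, month, day)


def format_partial_date(date: Optional[PartialDate]) -> str:
    """Inverse of :func:`parse_partial_date`; None → ''."""
    return "" if date is None else str(date)


def days_between(start: PartialDate, end: PartialDate) -> int:
    """end − start in whole days; both dates must be complete."""
    return end.to_ordinal() - start.to_ordinal()
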