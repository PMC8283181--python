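"""Imprecise-date handling for spontaneous-report files.

FAERS date fields carry 8-digit (YYYYMMDD), 6-digit (YYYYMM) or 4-digit
(YYYY) tokens, or are empty.  Precision must be preserved: day-level
arithmetic (e.g. time-to-onset) is only defined when both operands are
day-precise, otherwise downstream code treats the quantity as missing
rather than fabricating a value.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

__all__ = ["FuzzyDate", "parse_faers_date"]


@dataclass(frozen=True)
class FuzzyDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def sort_key(self) -> tuple:
        # missing components sort as the earliest possible value
        return (self.year, self.month or 1, self.day or 1)

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def to_date(self) -> _dt.date:
        """Exact date; only defined at day precision."""
        if self.precision != "day":
            raise ValueError(f"date has {self.precision} precision, not day")
        return _dt.date(self.year, self.month, self.day)

    def token(self) -> str:
        """Back to the FAERS digit-token form."""
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def __sub__(self, other: "FuzzyDate") -> int:
        """Whole days between two day-precision dates."""
        return (self.to_date() - other.to_date()).days


def parse_faers_date(token: object) -> Optional[FuzzyDate]:
    """Parse a FAERS date token; unparseable tokens give ``None``.

    Accepts 8-digit YYYYMMDD, 6-digit YYYYMM and 4-digit YYYY strings
    (surrounding whitespace and a trailing ``.0`` from numeric round-trips
    are tolerated).  Anything else — including calendar-invalid tokens
    such as ``20190230`` — is treated as missing.
    """
    if token is None:
        return None
    s = str(token).strip()
    if s.endswith(".0"):
        s = s[:-2]
    if not s.isdigit():
        return None
    if len(s) == 4:
        year = int(s)
        return FuzzyDate(year) if 1900 <= year <= 2100 else None
    if len(s) == 6:
        year, month = int(s[:4]), int(s[4:6])
        if 1900 <= year <= 2100 and 1 <= month <= 12:
            return FuzzyDate(year, month)
        return None
    if len(s) == 8:
        try:
            d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return None
        if not 1900 <= d.year <= 2100:
            return None
        return FuzzyDate(d.year, d.month, d.day)
    return None
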