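"""Partial calendar dates as they occur in FAERS date fields.

FAERS date columns (FDA_DT, EVENT_DT, START_DT, ...) hold bare digit
strings of 4, 6 or 8 characters: ``YYYY``, ``YYYYMM`` or ``YYYYMMDD``.
Spontaneous reports are dirty, so parsing never raises: a value is either
a :class:`PartialDate`, *missing* (empty field) or *invalid* (non-digit,
wrong length, or calendar-impossible like month 13 or Feb 30).
Calendar-invalid components demote the whole value to missing rather than
truncating to a coarser precision, so an "inaccurate date" can never leak
into a time-to-onset computation as a half-right one.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "PartialDate",
    "DateStatus",
    "MISSING",
    "INVALID",
    "parse_partial_date",
    "parse_partial_date_status",
]

# Parse-status labels. "day"/"month"/"year" mirror PartialDate.precision.
MISSING = "missing"
INVALID = "invalid"
DateStatus = str

_YEAR_LO, _YEAR_HI = 1900, 2100


@dataclass(frozen=True)
class PartialDate:
    """A date known to year, month or day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day requires month")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> Tuple[int, int, int]:
        """Chronological key; coarser precision sorts before finer within a period."""
        return (self.year, self.month or 0, self.day or 0)

    def to_string(self) -> str:
        """Round-trip back to the FAERS digit-string form."""
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def to_date(self) -> _dt.date:
        """Proleptic-Gregorian date; only defined at day precision."""
        if self.precision != "day":
            raise ValueError(f"not a full date: {self.to_string()}")
        return _dt.date(self.year, self.month, self.day)


def parse_partial_date_status(raw: Optional[str]) -> Tuple[Optional[PartialDate], DateStatus]:
    """Parse a FAERS date field, returning (value, status).

    Status is the value's precision when parseable, else ``"missing"``
    (empty/whitespace) or ``"invalid"`` (anything unparseable). Total over
    arbitrary input; never raises.
    """
    if raw is None:
        return None, MISSING
    s = raw.strip()
    if not s:
        return None, MISSING
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return None, INVALID
    year = int(s[:4])
    if not (_YEAR_LO <= year <= _YEAR_HI):
        return None, INVALID
    if len(s) == 4:
        return PartialDate(year), "year"
    month = int(s[4:6])
    if not (1 <= month <= 12):
        return None, INVALID
    if len(s) == 6:
        return PartialDate(year, month), "month"
    day = int(s[6:8])
    if not (1 <= day <= calendar.monthrange(year, month)[1]):
        return None, INVALID
    return PartialDate(year, month, day), "day"


def parse_partial_date(raw: Optional[str]) -> Optional[PartialDate]:
    """Parse a FAERS date field; missing and invalid both map to None."""
    return parse_partial_date_status(raw)[0]
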