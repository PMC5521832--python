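"""Partial calendar dates with explicit precision.

Spontaneous-reporting databases record administration and onset dates that
are often truncated to a month or a year. Time-to-onset statistics must know
the precision of each date so they can exclude sub-day-precision records
rather than silently imputing a day. A :class:`PartialDate` therefore always
carries a precision level; only day-precision dates convert to
:class:`datetime.date` and support day arithmetic.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from ._util import UserInputError


class DatePrecision(str, Enum):
    YEAR = "year"
    MONTH = "month"
    DAY = "day"


_ISO_RE = re.compile(r"^(\d{4})(?:-(\d{2}))?(?:-(\d{2}))?$")


@dataclass(frozen=True, order=True)
class PartialDate:
    """An ISO-8601 date truncated to year, month, or day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise UserInputError("a day requires a month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise UserInputError(f"month out of range: {self.month}")
        if self.day is not None:
            try:
                # delegates day-of-month validation (leap years etc.)
                datetime.date(self.year, self.month, self.day)
            except ValueError as exc:
                raise UserInputError(str(exc)) from exc

    @property
    def precision(self) -> DatePrecision:
        if self.day is not None:
            return DatePrecision.DAY
        if self.month is not None:
            return DatePrecision.MONTH
        return DatePrecision.YEAR

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse ``"2010"``, ``"2010-04"``, or ``"2010-04-07"``."""
        m = _ISO_RE.match(text.strip())
        if not m:
            raise UserInputError(f"unparseable date: {text!r}")
        y, mo, d = m.groups()
        return cls(int(y), int(mo) if mo else None, int(d) if d else None)

    @classmethod
    def parse_optional(cls, text: object) -> Optional["PartialDate"]:
        """Parse a cell that may be empty/missing; returns None for blanks."""
        if text is None:
            return None
        s = str(text).strip()
        if not s or s.lower() in {"nan", "none", "na"}:
            return None
        return cls.parse(s)

    def to_date(self) -> datetime.date:
        if self.precision is not DatePrecision.DAY:
            raise UserInputError(
                f"{self.isoformat()} has {self.precision.value} precision, not day"
            )
        return datetime.date(self.year, self.month, self.day)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.isoformat()


def days_between(start: PartialDate, end: PartialDate) -> int:
    """Signed day difference ``end - start``; both must be day-precision."""
    return (end.to_date() - start.to_date()).days
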