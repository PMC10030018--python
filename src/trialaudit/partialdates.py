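"""Partial calendar dates as they occur in trial registries.

Registry exports mix day-resolved dates ("2015-03-12"), month-resolved
dates ("March 2015", "2015-03") and bare years. The prospective-registration
rule compares registration and start dates at month granularity, so the
resolution of each date must be tracked explicitly rather than imputed.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import enum
import re
from dataclasses import dataclass
from typing import Optional


class Granularity(str, enum.Enum):
    YEAR = "year"
    MONTH = "month"
    DAY = "day"


class MonthOrder(str, enum.Enum):
    """Outcome of a month-level comparison between two partial dates."""

    BEFORE = "before"
    SAME = "same"
    AFTER = "after"
    UNDETERMINED = "undetermined"


class DateParseError(ValueError):
    """Raised when a date string cannot be interpreted; carries the input."""

    def __init__(self, text: str, reason: str = "unrecognised date format"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


@dataclass(frozen=True, order=False)
class PartialDate:
    """A Gregorian date known to year, month or day resolution.

    Invariants: a day requires a month; a month-less date has no day; any
    fully specified date must be a valid calendar date.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # validates the full date (raises for e.g. Feb 30)
            _dt.date(self.year, self.month, self.day)

    @property
    def granularity(self) -> Granularity:
        if self.day is not None:
            return Granularity.DAY
        if self.month is not None:
            return Granularity.MONTH
        return Granularity.YEAR

    def as_date(self, impute_day: int = 1, impute_month: int = 1) -> _dt.date:
        """Collapse to a ``datetime.date``, imputing missing components.

        Month-resolved dates are imputed to the first of the month by
        default (conservative for "within N years" checks).
        """
        month = self.month if self.month is not None else impute_month
        day = self.day if self.day is not None else impute_day
        day = min(day, calendar.monthrange(self.year, month)[1])
        return _dt.date(self.year, month, day)

    def add_years(self, years: int) -> "PartialDate":
        if self.month is not None and self.day is not None and self.month == 2 and self.day == 29:
            # Feb 29 + N years lands on Feb 28 in non-leap years
            if not calendar.isleap(self.year + years):
                return PartialDate(self.year + years, 2, 28)
        return PartialDate(self.year + years, self.month, self.day)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


_MONTH_NAMES = {name.lower(): i for i, name in enumerate(calendar.month_name) if name}
_MONTH_NAMES.update({name.lower(): i for i, name in enumerate(calendar.month_abbr) if name})

_ISO_DAY = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_ISO_MONTH = re.compile(r"^(\d{4})-(\d{1,2})$")
_YEAR = re.compile(r"^(\d{4})$")
_NAME_YEAR = re.compile(r"^([A-Za-z]+)\.?,?\s+(\d{4})$")
_NAME_DAY_YEAR = re.compile(r"^([A-Za-z]+)\.?\s+(\d{1,2}),?\s+(\d{4})$")
_DAY_NAME_YEAR = re.compile(r"^(\d{1,2})\.?\s+([A-Za-z]+)\.?\s+(\d{4})$")
_DOTTED_DMY = re.compile(r"^(\d{1,2})\.(\d{1,2})\.(\d{4})$")  # DRKS German style


def parse_partial_date(text: str) -> PartialDate:
    """Parse a free-form registry date at the finest expressible granularity.

    Accepted forms: ``2015-03-12``, ``2015-03``, ``2015``, ``March 2015``,
    ``March 12, 2015``, ``12 March 2015`` and the German ``12.03.2015``.
    Anything else raises :class:`DateParseError` — never a silent default.
    """
    if text is None:
        raise DateParseError(str(text), "empty date")
    s = str(text).strip()
    if not s:
        raise DateParseError(text, "empty date")
    try:
        if m := _ISO_DAY.match(s):
            return PartialDate(int(m[1]), int(m[2]), int(m[3]))
        if m := _ISO_MONTH.match(s):
            return PartialDate(int(m[1]), int(m[2]))
        if m := _YEAR.match(s):
            return PartialDate(int(m[1]))
        if m := _DOTTED_DMY.match(s):
            return PartialDate(int(m[3]), int(m[2]), int(m[1]))
        if m := _NAME_YEAR.match(s):
            month = _MONTH_NAMES.get(m[1].lower())
            if month:
                return PartialDate(int(m[2]), month)
        if m := _NAME_DAY_YEAR.match(s):
            month = _MONTH_NAMES.get(m[1].lower())
            if month:
                return PartialDate(int(m[3]), month, int(m[2]))
        if m := _DAY_NAME_YEAR.match(s):
            month = _MONTH_NAMES.get(m[2].lower())
            if month:
                return PartialDate(int(m[3]), month, int(m[1]))
    except ValueError as exc:
        raise DateParseError(text, str(exc)) from exc
    raise DateParseError(text)


def compare_month(a: Optional[PartialDate], b: Optional[PartialDate]) -> MonthOrder:
    """Compare two partial dates at month resolution.

    Day fields are ignored; if either operand lacks a month the comparison
    is :attr:`MonthOrder.UNDETERMINED`. This is the comparison behind the
    "registered in the same or a previous month" prospective-registration
    rule.
    """
    if a is None or b is None or a.month is None or b.month is None:
        return MonthOrder.UNDETERMINED
    ka, kb = (a.year, a.month), (b.year, b.month)
    if ka < kb:
        return MonthOrder.BEFORE
    if ka > kb:
        return MonthOrder.AFTER
    return MonthOrder.SAME
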