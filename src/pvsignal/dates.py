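"""Partial calendar dates with explicit completeness levels.

Spontaneous reports frequently carry dates known only to the year or
year-month; the canonical encoding is an ISO-8601 prefix ("2014",
"2014-03", "2014-03-21").  Only fully specified (YMD) dates are usable for
time-to-onset arithmetic; coarser dates are retained and the downstream
stage decides whether to use them.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional

_ISO_RE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")
_COMPACT_RE = re.compile(r"^(\d{4})(\d{2})?(\d{2})?$")


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date known to year (Y), year-month (YM) or full (YMD) precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # validates day-of-month (and leap years) via datetime
            _dt.date(self.year, self.month, self.day)

    @property
    def completeness(self) -> str:
        if self.day is not None:
            return "YMD"
        if self.month is not None:
            return "YM"
        return "Y"

    @property
    def is_complete(self) -> bool:
        return self.day is not None

    def to_date(self) -> _dt.date:
        if not self.is_complete:
            raise ValueError(f"partial date {self.isoformat()} has no day")
        return _dt.date(self.year, self.month, self.day)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def truncate(self, completeness: str) -> "PartialDate":
        """Drop precision down to ``completeness`` ('Y' or 'YM')."""
        if completeness == "Y":
            return PartialDate(self.year)
        if completeness == "YM":
            return PartialDate(self.year, self.month) if self.month else self
        return self

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def parse_partial_date(value) -> Optional[PartialDate]:
    """Parse an ISO prefix or FAERS-style compact date (YYYYMMDD / YYYYMM / YYYY).

    Returns None for empty, missing or unparseable values — tolerant by
    contract: a bad date never aborts a report row.
    """
    if value is None:
        return None
    if isinstance(value, PartialDate):
        return value
    if isinstance(value, _dt.date):
        return PartialDate(value.year, value.month, value.day)
    s = str(value).strip()
    if not s or s.lower() in {"nan", "none", "na"}:
        return None
    m = _ISO_RE.match(s) or _COMPACT_RE.match(s)
    if not m:
        return None
    year = int(m.group(1))
    month = int(m.group(2)) if m.group(2) else None
    day = int(m.group(3)) if m.group(3) else None
    # FAERS files sometimes carry month/day "00" meaning unknown
    if month == 0:
        month, day = None, None
    if day == 0:
        day = None
    try:
        return PartialDate(year, month, day)
    except ValueError:
        return None
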