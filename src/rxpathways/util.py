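"""Small date helpers shared across the pipeline.

All windows in the study design are expressed in whole months anchored at
day-resolution dates, so month arithmetic has to be explicit and
consistent: adding months clamps the day-of-month to the target month's
length (2017-01-31 + 1 month = 2017-02-28).
"""

from __future__ import annotations

import calendar
from datetime import date


def parse_iso_date(text: str) -> date:
    """Parse ``YYYY-MM-DD`` (or ``YYYY-MM``, meaning the first of the month)."""
    s = str(text).strip()
    parts = s.split("-")
    if len(parts) == 2:
        return date(int(parts[0]), int(parts[1]), 1)
    return date.fromisoformat(s)


def month_floor(d: date) -> date:
    return d.replace(day=1)


def add_months(d: date, n: int) -> date:
    """Shift ``d`` by ``n`` calendar months, clamping the day of month."""
    total = d.year * 12 + (d.month - 1) + n
    year, month0 = divmod(total, 12)
    month = month0 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def months_between(start: date, end: date) -> int:
    """Whole calendar months from ``start`` to ``end`` (floor; negative if end < start)."""
    n = (end.year - start.year) * 12 + (end.month - start.month)
    if end.day < start.day:
        n -= 1
    return n
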