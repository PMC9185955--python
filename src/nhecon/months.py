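"""Calendar-month arithmetic.

Months are the atomic time unit of the ledger: schedules, census rows and
salary spells are all indexed by ISO ``YYYY-MM`` tokens.  Dates inside a
month only matter for hospitalisation-episode bookkeeping, which works on
:class:`datetime.date` directly.
"""

from __future__ import annotations

import calendar
import datetime
import functools
import re
from dataclasses import dataclass

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


@functools.total_ordering
@dataclass(frozen=True)
class Month:
    """A calendar month, e.g. ``Month(2018, 6)`` for June 2018."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range 1-12: {self.month}")

    @classmethod
    def parse(cls, token: str) -> "Month":
        """Parse an ISO ``YYYY-MM`` token ("2018-06" -> June 2018)."""
        m = _MONTH_RE.match(str(token).strip())
        if m is None:
            raise ValueError(f"malformed month token: {token!r} (expected YYYY-MM)")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    # ordering -----------------------------------------------------------
    def _key(self) -> int:
        return self.year * 12 + (self.month - 1)

    def __lt__(self, other: "Month") -> bool:
        if not isinstance(other, Month):
            return NotImplemented
        return self._key() < other._key()

    # arithmetic ---------------------------------------------------------
    def add(self, n: int) -> "Month":
        """Month that lies ``n`` months after (``n`` may be negative)."""
        k = self._key() + n
        return Month(k // 12, k % 12 + 1)

    def diff(self, other: "Month") -> int:
        """Signed number of months from ``other`` to ``self``."""
        return self._key() - other._key()

    @property
    def days(self) -> int:
        """Number of calendar days in the month."""
        return calendar.monthrange(self.year, self.month)[1]

    def first_day(self) -> datetime.date:
        return datetime.date(self.year, self.month, 1)

    @classmethod
    def of(cls, d: datetime.date) -> "Month":
        return cls(d.year, d.month)


def month_range(start: Month, end: Month) -> list[Month]:
    """Inclusive list of months from ``start`` to ``end``."""
    if end < start:
        return []
    return [start.add(i) for i in range(end.diff(start) + 1)]
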