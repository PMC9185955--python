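"""Costing of the intervention itself: the nurse role in the expanded
clinical position.

The only marginal intervention cost is the nurse salary; the remaining care
elements are absorbed into ongoing facility processes at zero marginal cost.
``annual_gross`` is the full yearly amount including the 13th monthly
payment, so a month of work costs ``annual_gross x employment_fraction / 12``
and a full year of one record sums back to ``annual_gross x fraction``.
Bonuses and mid-period raises are out of scope: a pay change closes one
spell and opens another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .months import Month

#: Study staffing floor: 0.6 FTE per 80 beds = 0.75 FTE per 100 beds.
MIN_FTE_PER_100_BEDS = 0.75


class InterventionCostError(ValueError):
    pass


@dataclass(frozen=True)
class SalaryRecord:
    """One nurse employment spell with constant pay and employment fraction."""

    unit_id: str
    nurse_id: str
    annual_gross: float            # CHF/year, 13th month included
    employment_fraction: float     # fraction of full-time, (0, 1]
    active_from: Month
    active_to: Month

    def __post_init__(self) -> None:
        if self.annual_gross <= 0:
            raise InterventionCostError(f"annual_gross must be positive, got {self.annual_gross}")
        if not 0 < self.employment_fraction <= 1:
            raise InterventionCostError(
                f"employment_fraction must be in (0, 1], got {self.employment_fraction}")
        if self.active_to < self.active_from:
            raise InterventionCostError("active interval is empty")

    @property
    def active_months(self) -> int:
        return self.active_to.diff(self.active_from) + 1

    def is_active(self, month: Month) -> bool:
        return self.active_from <= month <= self.active_to


def monthly_salary_cost(record: SalaryRecord) -> float:
    """CHF cost of one active month: annual_gross x fraction / 12."""
    return record.annual_gross * record.employment_fraction / 12.0


def cost_per_bed_year(records: Iterable[SalaryRecord], beds: int) -> float:
    """Yearly nurse-salary cost per bed.

    Sum of ``annual_gross x fraction x active_months/12`` over records,
    divided by beds and by the active span (first active month to last, in
    years).  Invariant under splitting a record into consecutive spells at
    constant pay and fraction.  An empty record list reports 0 with a
    warning (the unit ran no intervention).
    """
    records = list(records)
    if beds <= 0:
        raise InterventionCostError(f"beds must be positive, got {beds}")
    if not records:
        warnings.warn("no salary records: unit ran no intervention", stacklevel=2)
        return 0.0
    total = sum(r.annual_gross * r.employment_fraction * r.active_months / 12.0 for r in records)
    span_start = min(r.active_from for r in records)
    span_end = max(r.active_to for r in records)
    span_years = (span_end.diff(span_start) + 1) / 12.0
    return total / beds / span_years


class Density(NamedTuple):
    headcount_per_100_beds: float
    fte_per_100_beds: float


def _per_nurse_fractions(records: list[SalaryRecord]) -> dict[str, float]:
    """Time-weighted employment fraction per distinct nurse."""
    months: dict[str, float] = {}
    weighted: dict[str, float] = {}
    for r in records:
        months[r.nurse_id] = months.get(r.nurse_id, 0.0) + r.active_months
        weighted[r.nurse_id] = weighted.get(r.nurse_id, 0.0) + r.employment_fraction * r.active_months
    return {n: weighted[n] / months[n] for n in months}


def icn_density(records: Iterable[SalaryRecord], beds: int,
                warn_below_minimum: bool = True) -> Density:
    """Nurse head-count and FTE per 100 beds.

    Emits a "below study minimum" warning when the FTE density falls under
    0.6 FTE per 80 beds (0.75 per 100).
    """
    records = list(records)
    if beds <= 0:
        raise InterventionCostError(f"beds must be positive, got {beds}")
    fractions = _per_nurse_fractions(records)
    headcount = len(fractions) / beds * 100.0
    fte = sum(fractions.values()) / beds * 100.0
    if warn_below_minimum and fte < MIN_FTE_PER_100_BEDS:
        warnings.warn(
            f"below study minimum staffing: {fte:.2f} FTE/100 beds < "
            f"{MIN_FTE_PER_100_BEDS} (0.6 FTE per 80 beds)", stacklevel=2)
    return Density(headcount, fte)


def mean_employment(records: Iterable[SalaryRecord]) -> float:
    """Unweighted mean employment fraction over distinct nurses."""
    fractions = _per_nurse_fractions(list(records))
    if not fractions:
        raise InterventionCostError("no salary records")
    return sum(fractions.values()) / len(fractions)
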