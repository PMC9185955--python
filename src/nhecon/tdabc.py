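"""Time-driven activity-based costing (TDABC) of the implementation effort.

Each implementation action is recorded as a process-map row stating what was
done, when, how often, for how long, by how many people and at what wage.
Personnel cost of a row is ``frequency x unit_duration x participants x
hourly_wage``; non-personnel resources (travel, material) add a flat CHF
amount.  Aggregation is per facility bed so that facilities of different
sizes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

#: The eight personnel action categories plus the two non-personnel ones.
RESEARCH_ORGANISED = (
    "preparatory_leadership_meetings",
    "meeting_all_nhs",
    "leadership_icn_meetings",
    "icn_training",
    "phone_calls",
)
NH_ORGANISED = (
    "internal_training_events",
    "administration",
    "internal_coordination",
)
NON_PERSONNEL = ("travel", "material")
CATEGORIES = RESEARCH_ORGANISED + NH_ORGANISED + NON_PERSONNEL

#: Categories whose time is reported "not applicable" (pure material spend).
TIMELESS_CATEGORIES = frozenset({"material"})


class TdabcError(ValueError):
    """Invalid process-map entry or aggregation request."""


@dataclass(frozen=True)
class ProcessMapEntry:
    """One implementation-strategy action record.

    ``participants_multiply`` lets a fixed-length offered session (one
    delivery regardless of head-count) bypass the participant multiplier in
    both the cost and the time formula.
    """

    unit_id: str
    category: str
    period: str = "intervention"
    frequency: float = 0.0
    unit_duration: float = 0.0
    participants: float = 0.0
    hourly_wage: float = 0.0
    nonpersonnel_cost: float = 0.0
    participants_multiply: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise TdabcError(f"unknown action category: {self.category!r}")
        for name in ("frequency", "unit_duration", "participants",
                     "hourly_wage", "nonpersonnel_cost"):
            if getattr(self, name) < 0:
                raise TdabcError(f"{name} must be nonnegative, got {getattr(self, name)}")


class ActionTime(NamedTuple):
    hours: float
    applicable: bool


def action_cost(entry: ProcessMapEntry) -> float:
    """CHF cost of one process-map row.

    ``frequency x unit_duration x participants x hourly_wage +
    nonpersonnel_cost`` (participants omitted when the entry opts out of the
    multiplier).  A pure material row, with zero frequency, reduces to its
    non-personnel term.
    """
    heads = entry.participants if entry.participants_multiply else 1.0
    return entry.frequency * entry.unit_duration * heads * entry.hourly_wage + entry.nonpersonnel_cost


def action_time(entry: ProcessMapEntry) -> ActionTime:
    """Person-hours of one row; material rows are flagged not-applicable."""
    if entry.category in TIMELESS_CATEGORIES:
        return ActionTime(0.0, False)
    heads = entry.participants if entry.participants_multiply else 1.0
    return ActionTime(entry.frequency * entry.unit_duration * heads, True)


@dataclass
class ImplementationCostReport:
    """Per-bed implementation cost and time, broken down by category.

    Totals are computed as the sum of the category values, so conservation
    holds exactly by construction.  Time for categories in
    ``time_not_applicable`` is carried as 0 in the total and flagged.
    """

    unit_id: str
    beds: int
    cost_per_bed: dict[str, float] = field(default_factory=dict)
    time_per_bed: dict[str, float] = field(default_factory=dict)
    time_not_applicable: frozenset[str] = frozenset()

    @property
    def total_cost_per_bed(self) -> float:
        return sum(self.cost_per_bed.values())

    @property
    def total_time_per_bed(self) -> float:
        return sum(self.time_per_bed.values())


def aggregate_per_bed(entries: Iterable[ProcessMapEntry], beds: int,
                      unit_id: str | None = None) -> ImplementationCostReport:
    """Aggregate process-map rows into a per-bed cost/time report.

    All entries must share one unit id; ``beds`` must be positive.  An empty
    entry list yields an all-zero report.
    """
    entries = list(entries)
    if beds <= 0:
        raise TdabcError(f"beds must be positive, got {beds}")
    ids = {e.unit_id for e in entries}
    if len(ids) > 1:
        raise TdabcError(f"entries span multiple units: {sorted(ids)}")
    if unit_id is None:
        unit_id = next(iter(ids)) if ids else ""

    cost: dict[str, float] = {}
    time: dict[str, float] = {}
    na: set[str] = set()
    for e in entries:
        cost[e.category] = cost.get(e.category, 0.0) + action_cost(e)
        hours, applicable = action_time(e)
        if applicable:
            time[e.category] = time.get(e.category, 0.0) + hours
        else:
            na.add(e.category)
    return ImplementationCostReport(
        unit_id=unit_id,
        beds=beds,
        cost_per_bed={c: v / beds for c, v in cost.items()},
        time_per_bed={c: v / beds for c, v in time.items()},
        time_not_applicable=frozenset(na),
    )


def category_share(report: ImplementationCostReport, categories: Iterable[str],
                   kind: str = "cost") -> float:
    """Fraction of the per-bed total (cost or time) in the named categories.

    The share of all categories is 1.0 by construction; an empty set gives
    0.0.  Raises on a zero total, where shares are undefined.
    """
    if kind == "cost":
        values, total = report.cost_per_bed, report.total_cost_per_bed
    elif kind == "time":
        values, total = report.time_per_bed, report.total_time_per_bed
    else:
        raise TdabcError(f"kind must be 'cost' or 'time', got {kind!r}")
    if total <= 0:
        raise TdabcError(f"category share undefined: total {kind} is zero")
    wanted = set(categories)
    unknown = wanted - set(CATEGORIES)
    if unknown:
        raise TdabcError(f"unknown categories: {sorted(unknown)}")
    return sum(v for c, v in values.items() if c in wanted) / total
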