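"""Revenue losses caused by resident hospitalisations, from the facility's
perspective.

While a resident is in hospital their bed is empty: nursing revenue from
insurers and public payers stops, and what happens to the resident's own
share of nursing fees and to the hotel (board and lodging) fee depends on
the facility's billing regime.  Savings in service costs are assumed to be
zero throughout — all service costs are treated as fixed.

Three regimes are modelled:

* ``A_reservation_fee`` — all nursing and hotel revenue stops, but the
  resident pays a flat daily reservation fee for the empty bed.
* ``B_hotel_continues`` — nursing revenue stops (all payers); the hotel fee
  continues to be billed.
* ``C_nursing_share_4_days`` — the resident's share of nursing fees and the
  hotel fee continue for the first four absence days; from day five the
  resident is additionally refunded a daily amount for meals/housekeeping.

Arrival and departure days are not absence days, so a one-night stay causes
no loss.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

REGIME_KINDS = ("A_reservation_fee", "B_hotel_continues", "C_nursing_share_4_days")

#: Absence days billed under the pre-refund rule in regime C.
REGIME_C_GRACE_DAYS = 4


class HospitalisationEconomicsError(ValueError):
    pass


@dataclass(frozen=True)
class BillingRegime:
    kind: str
    reservation_fee: float = 0.0   # CHF/day, regime A only
    daily_refund: float = 0.0      # CHF/day beyond day 4, regime C only

    def __post_init__(self) -> None:
        if self.kind not in REGIME_KINDS:
            raise HospitalisationEconomicsError(f"unknown billing regime: {self.kind!r}")
        if self.reservation_fee < 0 or self.daily_refund < 0:
            raise HospitalisationEconomicsError("regime parameters must be nonnegative")
        if self.kind != "A_reservation_fee" and self.reservation_fee != 0:
            raise HospitalisationEconomicsError("reservation_fee only applies to regime A")
        if self.kind != "C_nursing_share_4_days" and self.daily_refund != 0:
            raise HospitalisationEconomicsError("daily_refund only applies to regime C")


@dataclass(frozen=True)
class PriceSchedule:
    """Daily tariffs of one facility for one calendar year.

    ``nursing_level_revenue`` holds the twelve case-mix level tariffs
    (each level adds 20 minutes of daily care, up to 240); absent residents
    are valued at the simple average over the twelve levels.
    ``resident_nursing_share`` is the portion of the daily nursing revenue
    paid by the resident rather than by insurers/public payers.
    """

    unit_id: str
    year: int
    hotel_daily: float
    nursing_level_revenue: tuple[float, ...]
    resident_nursing_share: float
    regime: BillingRegime

    def __post_init__(self) -> None:
        if len(self.nursing_level_revenue) != 12:
            raise HospitalisationEconomicsError(
                f"expected 12 case-mix levels, got {len(self.nursing_level_revenue)}")
        if self.hotel_daily < 0 or any(v < 0 for v in self.nursing_level_revenue):
            raise HospitalisationEconomicsError("tariffs must be nonnegative")
        if self.resident_nursing_share < 0:
            raise HospitalisationEconomicsError("resident_nursing_share must be nonnegative")
        if self.resident_nursing_share > mean_nursing_revenue(self) * (1 + 1e-12) + 1e-9:
            raise HospitalisationEconomicsError(
                "resident_nursing_share exceeds mean nursing revenue")


@dataclass(frozen=True)
class HospitalisationEpisode:
    unit_id: str
    admission_date: datetime.date
    discharge_date: datetime.date

    def __post_init__(self) -> None:
        if self.discharge_date <= self.admission_date:
            raise HospitalisationEconomicsError(
                "discharge must follow admission by at least one night")


def absence_days(episode: HospitalisationEpisode) -> int:
    """Number of billable absence days: stay length minus the arrival and
    departure days (both excluded)."""
    return (episode.discharge_date - episode.admission_date).days - 1


def mean_nursing_revenue(schedule: PriceSchedule) -> float:
    """Simple (unweighted) mean over the 12 case-mix level tariffs."""
    return sum(schedule.nursing_level_revenue) / 12.0


class DailyLoss(NamedTuple):
    variable_loss: float   # CHF/day of revenue lost
    fixed_revenue: float   # CHF/day of revenue retained


def daily_loss(schedule: PriceSchedule, absence_day_index: int) -> DailyLoss:
    """Revenue split (lost vs retained) for the ``absence_day_index``-th
    absence day (1-based).

    Conservation holds by construction: lost + retained equals the full
    daily revenue, hotel fee plus mean nursing revenue.
    """
    if absence_day_index < 1:
        raise HospitalisationEconomicsError(
            f"absence day index must be >= 1, got {absence_day_index}")
    total = schedule.hotel_daily + mean_nursing_revenue(schedule)
    regime = schedule.regime
    if regime.kind == "A_reservation_fee":
        fixed = regime.reservation_fee
    elif regime.kind == "B_hotel_continues":
        fixed = schedule.hotel_daily
    else:  # C_nursing_share_4_days
        if absence_day_index <= REGIME_C_GRACE_DAYS:
            fixed = schedule.hotel_daily + schedule.resident_nursing_share
        else:
            # the resident's nursing share stops after day 4 and the
            # meals/housekeeping refund kicks in
            fixed = schedule.hotel_daily - regime.daily_refund
    return DailyLoss(variable_loss=total - fixed, fixed_revenue=fixed)


def episode_loss(episode: HospitalisationEpisode, schedule: PriceSchedule) -> float:
    """Total CHF revenue lost over the episode's absence days."""
    return sum(daily_loss(schedule, d).variable_loss
               for d in range(1, absence_days(episode) + 1))


def episode_savings(episode: HospitalisationEpisode,
                    schedule: PriceSchedule | None = None) -> float:
    """Service-cost savings during a hospitalisation: identically zero.

    All service costs are treated as fixed; the survey basis for the model
    found no quantifiable variable-cost savings.
    """
    return 0.0


@dataclass
class LossSummary:
    unit_id: str
    n_episodes: int
    n_absence_days: int
    mean_daily_variable_loss: float | None
    mean_daily_fixed_revenue: float | None
    percent_revenue_lost: float | None   # fraction in [0, 1], None when undefined
    total_variable_loss: float = 0.0
    total_savings: float = 0.0


def _schedule_for(schedules: dict[tuple[str, int], PriceSchedule],
                  unit_id: str, year: int) -> PriceSchedule:
    key = (unit_id, year)
    if key in schedules:
        return schedules[key]
    # fall back to the unit's nearest available year
    years = sorted(y for (u, y) in schedules if u == unit_id)
    if not years:
        raise HospitalisationEconomicsError(f"no price schedule for unit {unit_id!r}")
    nearest = min(years, key=lambda y: abs(y - year))
    return schedules[(unit_id, nearest)]


def loss_summary(episodes: Iterable[HospitalisationEpisode],
                 schedules: Iterable[PriceSchedule]) -> tuple[list[LossSummary], LossSummary]:
    """Per-unit and pooled revenue-loss summary.

    Episodes are priced with the schedule of their admission year (nearest
    available year as fallback).  The pooled row averages the per-unit
    daily means and loss percentages unweighted across units; with all-zero
    tariffs the percentage is undefined and reported as ``None``.
    """
    by_year = {(s.unit_id, s.year): s for s in schedules}
    per_unit: dict[str, dict[str, float]] = {}
    for ep in episodes:
        sched = _schedule_for(by_year, ep.unit_id, ep.admission_date.year)
        acc = per_unit.setdefault(ep.unit_id, {"var": 0.0, "fix": 0.0, "days": 0, "eps": 0})
        for d in range(1, absence_days(ep) + 1):
            var, fix = daily_loss(sched, d)
            acc["var"] += var
            acc["fix"] += fix
            acc["days"] += 1
        acc["eps"] += 1

    rows: list[LossSummary] = []
    for unit_id in sorted(per_unit):
        acc = per_unit[unit_id]
        days = int(acc["days"])
        if days == 0:
            rows.append(LossSummary(unit_id, int(acc["eps"]), 0, None, None, None))
            continue
        mean_var = acc["var"] / days
        mean_fix = acc["fix"] / days
        revenue = mean_var + mean_fix
        pct = mean_var / revenue if revenue > 0 else None
        rows.append(LossSummary(unit_id, int(acc["eps"]), days, mean_var, mean_fix, pct,
                                total_variable_loss=acc["var"]))

    with_days = [r for r in rows if r.n_absence_days > 0]
    if with_days:
        mv = sum(r.mean_daily_variable_loss for r in with_days) / len(with_days)
        mf = sum(r.mean_daily_fixed_revenue for r in with_days) / len(with_days)
        pcts = [r.percent_revenue_lost for r in with_days if r.percent_revenue_lost is not None]
        pct = sum(pcts) / len(pcts) if pcts else None
        pooled = LossSummary("pooled", sum(r.n_episodes for r in rows),
                             sum(r.n_absence_days for r in rows), mv, mf, pct,
                             total_variable_loss=sum(r.total_variable_loss for r in rows))
    else:
        pooled = LossSummary("pooled", sum(r.n_episodes for r in rows), 0, None, None, None)
    return rows, pooled
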