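"""Synthetic stepped-wedge ledger generator.

Builds complete, internally consistent ledgers with the statistical
structure the downstream analysis assumes: seven analytic units (six single
facilities plus one pooled multi-site group), sequential starts of 1-2
units per month, monthly census with Poisson hospitalisation counts whose
rate drops from the pre-intervention to the intervention level, nurse
salary spells drawn from the observed salary range, a full process map and
yearly price schedules.

Randomness is driven by a single integer seed split into named substreams
(schedules, census, salaries, process map, prices, episodes), so adding a
table never perturbs the draws of an earlier one.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field

import numpy as np
import yaml

from .hospital import BillingRegime, HospitalisationEpisode, PriceSchedule
from .intervention import SalaryRecord
from .ledger import Ledger, MonthlyCensus, NursingHomeUnit, StudySchedule
from .months import Month, month_range
from .tdabc import ProcessMapEntry

#: Substream indices; append only, never reorder.
_STREAMS = ("schedules", "census", "salaries", "process_map", "prices", "episodes")

#: Fixed offered durations of the research-organised actions (hours).
PREPARATORY_MEETING_HOURS = (8.0, 3.0, 3.0)   # three leadership meetings
ALL_NH_MEETING_HOURS = 7.0
LEADERSHIP_MEETING_HOURS = 2.0                # per meeting, bi-monthly
ICN_TRAINING_HOURS = 390.0                    # blended learning curriculum
PHONE_CALLS_PER_MONTH = 2                     # one hour each, with the nurse
PHONE_CALL_HOURS = 1.0

#: First unit starts its transition September 2018; census history begins
#: January 2017 so every unit carries >= 17 pre-study months.
CENSUS_START = Month(2017, 1)
FIRST_TRANSITION = Month(2018, 9)


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable knobs of the ledger generator (all rates and prices in CHF).

    ``target_salary_rate`` calibrates employment fractions so the expected
    intervention-period salary rate matches the stated mean; set to ``None``
    to draw fractions uniformly from ``employment_range`` instead.
    ``rate_jitter_sd`` optionally adds between-unit log-normal variation to
    the hospitalisation rates; ``overdispersion`` switches the monthly
    counts from Poisson to negative binomial with that dispersion.
    """

    n_units: int = 7
    beds_range: tuple[int, int] = (60, 120)
    group_site_beds_range: tuple[int, int] = (40, 90)   # 5 pooled sites
    pre_rate: float = 1.27       # hospitalisations per 1000 nursing days
    post_rate: float = 1.14
    occupancy: float = 0.95
    salary_range: tuple[float, float] = (68_738.0, 97_500.0)
    icn_density_range: tuple[float, float] = (0.8, 2.0)  # nurses per 100 beds
    employment_range: tuple[float, float] = (0.40, 1.00)
    intervention_months_range: tuple[int, int] = (12, 17)
    target_salary_rate: float | None = 2937.0            # CHF per 1000 nursing days
    nh_action_intensity: float = 1.0
    hotel_range: tuple[float, float] = (140.0, 165.0)
    nursing_level1_range: tuple[float, float] = (45.0, 55.0)
    nursing_level_step: float = 17.0
    resident_share_range: tuple[float, float] = (18.0, 28.0)
    reservation_fee_range: tuple[float, float] = (100.0, 160.0)
    daily_refund_range: tuple[float, float] = (8.0, 15.0)
    mean_extra_nights: float = 5.0       # episode length = 1 + Poisson(this)
    rate_jitter_sd: float = 0.0
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beds_range", "group_site_beds_range", "salary_range",
                     "icn_density_range", "employment_range",
                     "intervention_months_range", "hotel_range",
                     "nursing_level1_range", "resident_share_range",
                     "reservation_fee_range", "daily_refund_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise GeneratorConfigError(f"{name} is inverted: {lo} > {hi}")
        if self.pre_rate < 0 or self.post_rate < 0:
            raise GeneratorConfigError("rates must be nonnegative")
        if not 0 < self.occupancy <= 1:
            raise GeneratorConfigError(f"occupancy must be in (0, 1], got {self.occupancy}")
        if self.n_units < 1:
            raise GeneratorConfigError("n_units must be >= 1")
        lo, hi = self.intervention_months_range
        if not (12 <= lo and hi <= 17):
            raise GeneratorConfigError("intervention_months_range must lie within 12-17")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise GeneratorConfigError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(idx,)))


def draw_monthly_hospitalisations(rate: float, nursing_days: int,
                                  rng: np.random.Generator,
                                  overdispersion: float | None = None) -> int:
    """Poisson count with mean ``rate x nursing_days / 1000``.

    With ``overdispersion`` k the count is negative binomial with the same
    mean and variance ``mean x (1 + mean/k)``.
    """
    if rate < 0:
        raise GeneratorConfigError(f"rate must be nonnegative, got {rate}")
    if nursing_days < 0:
        raise GeneratorConfigError(f"nursing_days must be nonnegative, got {nursing_days}")
    mean = rate * nursing_days / 1000.0
    if mean == 0:
        return 0
    if overdispersion is None:
        return int(rng.poisson(mean))
    k = float(overdispersion)
    return int(rng.negative_binomial(k, k / (k + mean)))


def draw_salary(salary_range: tuple[float, float], rng: np.random.Generator) -> float:
    """Annual gross salary, uniform over the closed interval."""
    lo, hi = salary_range
    if lo > hi:
        raise GeneratorConfigError(f"salary interval inverted: {lo} > {hi}")
    return float(rng.uniform(lo, hi))


def _draw_schedules(config: GeneratorConfig, rng: np.random.Generator) -> list[StudySchedule]:
    """Sequential stepped-wedge starts: 1-2 units begin each month."""
    offsets: list[int] = []
    current = 0
    in_month = 0
    for _ in range(config.n_units):
        offsets.append(current)
        in_month += 1
        if in_month == 2 or rng.random() < 0.5:
            current += 1
            in_month = 0
    schedules = []
    lo, hi = config.intervention_months_range
    for off in offsets:
        transition = FIRST_TRANSITION.add(off)
        baseline = transition.add(-3)
        preparatory = baseline.add(-int(rng.integers(2, 5)))
        start = transition.add(1)
        end = start.add(int(rng.integers(lo, hi + 1)) - 1)
        schedules.append(StudySchedule(preparatory, baseline, transition, start, end))
    return schedules


def _draw_units(config: GeneratorConfig, schedules: list[StudySchedule],
                rng: np.random.Generator) -> list[NursingHomeUnit]:
    units = []
    for i, sched in enumerate(schedules):
        if i == config.n_units - 1 and config.n_units >= 2:
            # the last unit is the five-site group, reported pooled
            lo, hi = config.group_site_beds_range
            beds = int(rng.integers(lo, hi + 1, size=5).sum())
            unit_id = "GRP"
        else:
            lo, hi = config.beds_range
            beds = int(rng.integers(lo, hi + 1))
            unit_id = f"NH{i + 1}"
        units.append(NursingHomeUnit(unit_id, beds, sched))
    return units


def _nursing_days(beds: int, month: Month, occupancy: float) -> int:
    return int(round(beds * month.days * occupancy))


def _draw_census(config: GeneratorConfig, units: list[NursingHomeUnit],
                 rng: np.random.Generator) -> list[MonthlyCensus]:
    census = []
    for u in units:
        jitter = float(np.exp(rng.normal(0.0, config.rate_jitter_sd))) \
            if config.rate_jitter_sd > 0 else 1.0
        for m in month_range(CENSUS_START, u.schedule.intervention_end):
            days = _nursing_days(u.beds, m, config.occupancy)
            # implementation begins in the transition month, so transition
            # and intervention months draw at the post rate
            rate = config.pre_rate if m < u.schedule.transition_start else config.post_rate
            count = draw_monthly_hospitalisations(rate * jitter, days, rng,
                                                  config.overdispersion)
            census.append(MonthlyCensus(u.unit_id, m, days, count))
    return census


def _draw_salaries(config: GeneratorConfig, units: list[NursingHomeUnit],
                   rng: np.random.Generator) -> list[SalaryRecord]:
    records = []
    emp_lo, emp_hi = config.employment_range
    for u in units:
        lo, hi = config.icn_density_range
        density = float(rng.uniform(lo, hi))
        n_icn = max(1, round(density * u.beds / 100.0))
        salaries = [draw_salary(config.salary_range, rng) for _ in range(n_icn)]
        if config.target_salary_rate is not None:
            # mean monthly nursing days over the intervention window
            months = month_range(u.schedule.intervention_start, u.schedule.intervention_end)
            mean_days = float(np.mean([_nursing_days(u.beds, m, config.occupancy)
                                       for m in months]))
            needed_monthly = config.target_salary_rate * mean_days / 1000.0
            needed_annual = needed_monthly * 12.0
            # top up the team when full-time work cannot cover the target
            while sum(salaries) < needed_annual:
                salaries.append(draw_salary(config.salary_range, rng))
            utilisation = needed_annual / sum(salaries)
            fractions = [min(1.0, max(emp_lo, utilisation)) for _ in salaries]
        else:
            fractions = [float(rng.uniform(emp_lo, emp_hi)) for _ in salaries]
        for j, (annual, frac) in enumerate(zip(salaries, fractions)):
            records.append(SalaryRecord(
                unit_id=u.unit_id, nurse_id=f"{u.unit_id}-ICN{j + 1}",
                annual_gross=annual, employment_fraction=frac,
                active_from=u.schedule.intervention_start,
                active_to=u.schedule.intervention_end))
    return records


def generate_process_map(unit: NursingHomeUnit, config: GeneratorConfig,
                         rng: np.random.Generator,
                         n_icn: int = 1) -> list[ProcessMapEntry]:
    """Process-map rows for one unit, covering all eight action categories.

    Research-organised actions carry their fixed offered durations (three
    preparatory meetings of 8+3+3 h, a 7 h all-facility meeting, 2 h
    bi-monthly leadership meetings, the 390 h nurse curriculum, and
    twice-monthly one-hour phone calls); facility-organised actions are
    drawn from configurable intensity ranges and disappear entirely at
    intensity zero.
    """
    sched = unit.schedule
    entries: list[ProcessMapEntry] = []
    uid = unit.unit_id
    wage = float(rng.uniform(45.0, 80.0))          # leadership/mixed wage
    icn_wage = float(rng.uniform(40.0, 55.0))

    prep_participants = int(rng.integers(2, 13))
    for hours in PREPARATORY_MEETING_HOURS:
        entries.append(ProcessMapEntry(
            uid, "preparatory_leadership_meetings", "preparatory",
            frequency=1, unit_duration=hours,
            participants=prep_participants, hourly_wage=wage))

    entries.append(ProcessMapEntry(
        uid, "meeting_all_nhs", "intervention",
        frequency=1, unit_duration=ALL_NH_MEETING_HOURS,
        participants=int(rng.integers(0, 9)), hourly_wage=wage))

    # bi-monthly leadership meetings during transition + intervention
    span = sched.intervention_months + 1
    entries.append(ProcessMapEntry(
        uid, "leadership_icn_meetings", "intervention",
        frequency=-(-span // 2), unit_duration=LEADERSHIP_MEETING_HOURS,
        participants=int(rng.integers(3, 9)), hourly_wage=wage))

    entries.append(ProcessMapEntry(
        uid, "icn_training", "intervention",
        frequency=1, unit_duration=ICN_TRAINING_HOURS,
        participants=n_icn, hourly_wage=icn_wage))

    # twice-monthly one-hour calls throughout baseline/transition/intervention
    call_months = 3 + 1 + sched.intervention_months
    entries.append(ProcessMapEntry(
        uid, "phone_calls", "intervention",
        frequency=PHONE_CALLS_PER_MONTH * call_months,
        unit_duration=PHONE_CALL_HOURS,
        participants=n_icn, hourly_wage=icn_wage))

    k = config.nh_action_intensity
    if k > 0:
        staff_wage = float(rng.uniform(35.0, 55.0))
        entries.append(ProcessMapEntry(
            uid, "internal_training_events", "intervention",
            frequency=max(1, round(k * int(rng.integers(3, 10)))),
            unit_duration=float(rng.uniform(1.0, 3.0)),
            participants=int(rng.integers(5, 31)), hourly_wage=staff_wage))
        entries.append(ProcessMapEntry(
            uid, "administration", "intervention",
            frequency=max(1, round(k * int(rng.integers(10, 40)))),
            unit_duration=float(rng.uniform(1.0, 4.0)),
            participants=int(rng.integers(1, 4)), hourly_wage=staff_wage))
        entries.append(ProcessMapEntry(
            uid, "internal_coordination", "intervention",
            frequency=max(1, round(k * int(rng.integers(5, 25)))),
            unit_duration=float(rng.uniform(0.5, 2.5)),
            participants=int(rng.integers(1, 5)), hourly_wage=staff_wage))

    entries.append(ProcessMapEntry(
        uid, "travel", "intervention",
        frequency=int(rng.integers(4, 11)), unit_duration=float(rng.uniform(0.5, 2.0)),
        participants=int(rng.integers(1, 5)), hourly_wage=0.0,
        nonpersonnel_cost=float(rng.uniform(500.0, 3500.0))))
    material = 0.0 if rng.random() < 0.2 else float(rng.uniform(100.0, 5000.0))
    entries.append(ProcessMapEntry(
        uid, "material", "intervention", nonpersonnel_cost=material))
    return entries


def _draw_prices(config: GeneratorConfig, units: list[NursingHomeUnit],
                 rng: np.random.Generator) -> list[PriceSchedule]:
    prices = []
    kinds = ("A_reservation_fee", "B_hotel_continues", "C_nursing_share_4_days")
    for u in units:
        kind = kinds[int(rng.integers(0, 3))]
        hotel = float(rng.uniform(*config.hotel_range))
        level1 = float(rng.uniform(*config.nursing_level1_range))
        share = float(rng.uniform(*config.resident_share_range))
        fee = float(rng.uniform(*config.reservation_fee_range)) \
            if kind == "A_reservation_fee" else 0.0
        refund = float(rng.uniform(*config.daily_refund_range)) \
            if kind == "C_nursing_share_4_days" else 0.0
        for year in range(CENSUS_START.year, u.schedule.intervention_end.year + 1):
            drift = 1.0 + 0.015 * (year - CENSUS_START.year)   # nursing tariffs rise
            levels = tuple(round((level1 + config.nursing_level_step * i) * drift, 2)
                           for i in range(12))
            prices.append(PriceSchedule(
                unit_id=u.unit_id, year=year, hotel_daily=round(hotel, 2),
                nursing_level_revenue=levels,
                resident_nursing_share=round(share, 2),
                regime=BillingRegime(kind, reservation_fee=fee, daily_refund=refund)))
    return prices


def _draw_episodes(census: list[MonthlyCensus], config: GeneratorConfig,
                   rng: np.random.Generator) -> list[HospitalisationEpisode]:
    """Admission/discharge date pairs consistent with the census counts."""
    episodes = []
    for c in census:
        for _ in range(c.hospitalisations):
            day = int(rng.integers(1, c.month.days + 1))
            admission = datetime.date(c.month.year, c.month.month, day)
            nights = 1 + int(rng.poisson(config.mean_extra_nights))
            episodes.append(HospitalisationEpisode(
                c.unit_id, admission, admission + datetime.timedelta(days=nights)))
    return episodes


def generate_ledger(config: GeneratorConfig) -> Ledger:
    """Generate a complete synthetic ledger, deterministic given the seed."""
    sched_rng = _rng(config, "schedules")
    schedules = _draw_schedules(config, sched_rng)
    units = _draw_units(config, schedules, sched_rng)
    census = _draw_census(config, units, _rng(config, "census"))
    salaries = _draw_salaries(config, units, _rng(config, "salaries"))

    icn_by_unit = {u.unit_id: sum(1 for s in salaries if s.unit_id == u.unit_id)
                   for u in units}
    pm_rng = _rng(config, "process_map")
    process_map = []
    for u in units:
        process_map.extend(generate_process_map(u, config, pm_rng,
                                                n_icn=icn_by_unit[u.unit_id]))

    prices = _draw_prices(config, units, _rng(config, "prices"))
    episodes = _draw_episodes(census, config, _rng(config, "episodes"))
    return Ledger(units=units, census=census, process_map=process_map,
                  salaries=salaries, prices=prices, episodes=episodes)
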