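"""Canonical data model for the facility ledger and its delimited-text I/O.

A ledger bundles five tables — units (with their stepped-wedge schedules),
monthly census, implementation process map, nurse salary spells and price
schedules — plus optional hospitalisation episodes.  All money is CHF;
values are kept unrounded internally and rounded (half away from zero) to
two decimals only at report time via :func:`format_chf`.
"""

from __future__ import annotations

import datetime
import decimal
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hospital import BillingRegime, HospitalisationEpisode, PriceSchedule
from .intervention import SalaryRecord
from .months import Month
from .tdabc import ProcessMapEntry

PERIOD_LABELS = ("preparatory", "baseline", "transition", "intervention", "out_of_study")

BASELINE_MONTHS = 3      # baseline measurement spans exactly three months
TRANSITION_MONTHS = 1    # one-month transition between baseline and intervention
MIN_INTERVENTION_MONTHS = 12
MAX_INTERVENTION_MONTHS = 17
MIN_BEDS = 60            # inclusion criterion (warning-level)


class LedgerFormatError(ValueError):
    """Raised by the readers on malformed or incomplete input tables."""


@dataclass(frozen=True)
class StudySchedule:
    """Stepped-wedge period boundaries for one unit (all months inclusive
    of their label's start; ``intervention_end`` is the last study month)."""

    preparatory_start: Month
    baseline_start: Month
    transition_start: Month
    intervention_start: Month
    intervention_end: Month

    def check(self) -> list[str]:
        """Rule names violated by this schedule (empty when valid)."""
        problems = []
        if not (self.preparatory_start <= self.baseline_start):
            problems.append("preparatory precedes baseline")
        if self.transition_start.diff(self.baseline_start) != BASELINE_MONTHS:
            problems.append("baseline spans exactly 3 months")
        if self.intervention_start.diff(self.transition_start) != TRANSITION_MONTHS:
            problems.append("transition spans exactly 1 month")
        length = self.intervention_end.diff(self.intervention_start) + 1
        if not MIN_INTERVENTION_MONTHS <= length <= MAX_INTERVENTION_MONTHS:
            problems.append("intervention length is 12-17 months")
        return problems

    @property
    def intervention_months(self) -> int:
        return self.intervention_end.diff(self.intervention_start) + 1


def assign_period(schedule: StudySchedule, month: Month) -> str:
    """Period label of ``month`` under ``schedule``.

    Labels partition the window: every month maps to exactly one of
    preparatory / baseline / transition / intervention / out_of_study.
    """
    if month < schedule.preparatory_start or schedule.intervention_end < month:
        return "out_of_study"
    if month < schedule.baseline_start:
        return "preparatory"
    if month < schedule.transition_start:
        return "baseline"
    if month < schedule.intervention_start:
        return "transition"
    return "intervention"


@dataclass(frozen=True)
class NursingHomeUnit:
    """One analytic unit: a single facility, or a multi-site group reported
    jointly (pooled beds, one schedule)."""

    unit_id: str
    beds: int
    schedule: StudySchedule


@dataclass(frozen=True)
class MonthlyCensus:
    unit_id: str
    month: Month
    nursing_days: int
    hospitalisations: int    # admissions with >= 1 overnight stay


@dataclass(frozen=True)
class Violation:
    rule: str
    ref: str
    severity: str = "error"   # "error" | "warning"


@dataclass
class Ledger:
    units: list[NursingHomeUnit] = field(default_factory=list)
    census: list[MonthlyCensus] = field(default_factory=list)
    process_map: list[ProcessMapEntry] = field(default_factory=list)
    salaries: list[SalaryRecord] = field(default_factory=list)
    prices: list[PriceSchedule] = field(default_factory=list)
    episodes: list[HospitalisationEpisode] = field(default_factory=list)

    def unit(self, unit_id: str) -> NursingHomeUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"unknown unit_id: {unit_id!r}")


def validate_ledger(ledger: Ledger) -> list[Violation]:
    """Collect invariant violations; never raises, never mutates.

    An empty result means every type invariant and cross-table foreign key
    holds.  Warning-level findings (e.g. the 60-bed inclusion criterion)
    are reported with severity "warning".
    """
    out: list[Violation] = []
    known = set()
    for u in ledger.units:
        if u.unit_id in known:
            out.append(Violation("duplicate unit_id", f"units:{u.unit_id}"))
        known.add(u.unit_id)
        if u.beds <= 0:
            out.append(Violation("positive beds", f"units:{u.unit_id}"))
        elif u.beds < MIN_BEDS:
            out.append(Violation("beds >= 60 inclusion criterion",
                                 f"units:{u.unit_id}", severity="warning"))
        for rule in u.schedule.check():
            out.append(Violation(rule, f"units:{u.unit_id}"))

    def fk(unit_id: str, ref: str) -> None:
        if unit_id not in known:
            out.append(Violation("foreign key", ref))

    seen_census = set()
    for i, c in enumerate(ledger.census):
        ref = f"census:{c.unit_id}:{c.month}"
        fk(c.unit_id, ref)
        if (c.unit_id, c.month) in seen_census:
            out.append(Violation("duplicate census month", ref))
        seen_census.add((c.unit_id, c.month))
        if c.nursing_days < 0:
            out.append(Violation("nonnegative nursing_days", ref))
        if c.hospitalisations < 0:
            out.append(Violation("nonnegative hospitalisations", ref))

    for i, e in enumerate(ledger.process_map):
        fk(e.unit_id, f"process_map:{i}")

    for i, s in enumerate(ledger.salaries):
        ref = f"salaries:{s.unit_id}:{s.nurse_id}"
        fk(s.unit_id, ref)
        if s.unit_id in known:
            sched = ledger.unit(s.unit_id).schedule
            if s.active_from < sched.intervention_start or sched.intervention_end < s.active_to:
                out.append(Violation("salary spell within intervention period", ref))

    for p in ledger.prices:
        fk(p.unit_id, f"prices:{p.unit_id}:{p.year}")

    for i, ep in enumerate(ledger.episodes):
        fk(ep.unit_id, f"episodes:{i}")
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

TABLE_FILES = {
    "units": "units.csv",
    "census": "census.csv",
    "process_map": "process_map.csv",
    "salaries": "salaries.csv",
    "prices": "prices.csv",
    "episodes": "episodes.csv",   # optional
}

_LEVEL_COLS = [f"level_{i}" for i in range(1, 13)]

_REQUIRED_COLUMNS = {
    "units": ["unit_id", "beds", "preparatory_start", "baseline_start",
              "transition_start", "intervention_start", "intervention_end"],
    "census": ["unit_id", "month", "nursing_days", "hospitalisations"],
    "process_map": ["unit_id", "category", "period", "frequency", "unit_duration",
                    "participants", "hourly_wage", "nonpersonnel_cost",
                    "participants_multiply"],
    "salaries": ["unit_id", "nurse_id", "annual_gross", "employment_fraction",
                 "active_from", "active_to"],
    "prices": ["unit_id", "year", "hotel_daily", *_LEVEL_COLS,
               "resident_nursing_share", "regime", "reservation_fee", "daily_refund"],
    "episodes": ["unit_id", "admission_date", "discharge_date"],
}


def _read_table(path: Path, name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise LedgerFormatError(f"missing table file {path}") from None
    for col in _REQUIRED_COLUMNS[name]:
        if col not in df.columns:
            raise LedgerFormatError(f"{path.name}: missing column {col}")
    return df


def _parse_month(token, where: str) -> Month:
    try:
        return Month.parse(token)
    except ValueError as exc:
        raise LedgerFormatError(f"{where}: {exc}") from None


def load_ledger(path: str | Path) -> Ledger:
    """Read a ledger from a directory of delimited tables.

    Raises :class:`LedgerFormatError` naming the offending column or row on
    malformed input; episodes.csv is optional.
    """
    path = Path(path)
    ledger = Ledger()

    df = _read_table(path / TABLE_FILES["units"], "units")
    for i, row in df.iterrows():
        where = f"units.csv row {i}"
        sched = StudySchedule(*(
            _parse_month(row[c], where) for c in
            ("preparatory_start", "baseline_start", "transition_start",
             "intervention_start", "intervention_end")))
        ledger.units.append(NursingHomeUnit(str(row["unit_id"]), int(row["beds"]), sched))

    df = _read_table(path / TABLE_FILES["census"], "census")
    for i, row in df.iterrows():
        ledger.census.append(MonthlyCensus(
            str(row["unit_id"]), _parse_month(row["month"], f"census.csv row {i}"),
            int(row["nursing_days"]), int(row["hospitalisations"])))

    df = _read_table(path / TABLE_FILES["process_map"], "process_map")
    for _, row in df.iterrows():
        ledger.process_map.append(ProcessMapEntry(
            unit_id=str(row["unit_id"]), category=str(row["category"]),
            period=str(row["period"]), frequency=float(row["frequency"]),
            unit_duration=float(row["unit_duration"]),
            participants=float(row["participants"]),
            hourly_wage=float(row["hourly_wage"]),
            nonpersonnel_cost=float(row["nonpersonnel_cost"]),
            participants_multiply=bool(row["participants_multiply"])))

    df = _read_table(path / TABLE_FILES["salaries"], "salaries")
    for i, row in df.iterrows():
        where = f"salaries.csv row {i}"
        ledger.salaries.append(SalaryRecord(
            unit_id=str(row["unit_id"]), nurse_id=str(row["nurse_id"]),
            annual_gross=float(row["annual_gross"]),
            employment_fraction=float(row["employment_fraction"]),
            active_from=_parse_month(row["active_from"], where),
            active_to=_parse_month(row["active_to"], where)))

    df = _read_table(path / TABLE_FILES["prices"], "prices")
    for _, row in df.iterrows():
        regime = BillingRegime(kind=str(row["regime"]),
                               reservation_fee=float(row["reservation_fee"]),
                               daily_refund=float(row["daily_refund"]))
        ledger.prices.append(PriceSchedule(
            unit_id=str(row["unit_id"]), year=int(row["year"]),
            hotel_daily=float(row["hotel_daily"]),
            nursing_level_revenue=tuple(float(row[c]) for c in _LEVEL_COLS),
            resident_nursing_share=float(row["resident_nursing_share"]),
            regime=regime))

    ep_path = path / TABLE_FILES["episodes"]
    if ep_path.exists():
        df = _read_table(ep_path, "episodes")
        for i, row in df.iterrows():
            try:
                adm = datetime.date.fromisoformat(str(row["admission_date"]))
                dis = datetime.date.fromisoformat(str(row["discharge_date"]))
            except ValueError as exc:
                raise LedgerFormatError(f"episodes.csv row {i}: {exc}") from None
            ledger.episodes.append(HospitalisationEpisode(str(row["unit_id"]), adm, dis))
    return ledger


def save_ledger(ledger: Ledger, path: str | Path) -> None:
    """Write the ledger tables; write-then-read round-trips losslessly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([{
        "unit_id": u.unit_id, "beds": u.beds,
        "preparatory_start": str(u.schedule.preparatory_start),
        "baseline_start": str(u.schedule.baseline_start),
        "transition_start": str(u.schedule.transition_start),
        "intervention_start": str(u.schedule.intervention_start),
        "intervention_end": str(u.schedule.intervention_end),
    } for u in ledger.units]).to_csv(path / TABLE_FILES["units"], index=False)

    pd.DataFrame([{
        "unit_id": c.unit_id, "month": str(c.month),
        "nursing_days": c.nursing_days, "hospitalisations": c.hospitalisations,
    } for c in ledger.census]).to_csv(path / TABLE_FILES["census"], index=False)

    pd.DataFrame([{
        "unit_id": e.unit_id, "category": e.category, "period": e.period,
        "frequency": e.frequency, "unit_duration": e.unit_duration,
        "participants": e.participants, "hourly_wage": e.hourly_wage,
        "nonpersonnel_cost": e.nonpersonnel_cost,
        "participants_multiply": e.participants_multiply,
    } for e in ledger.process_map]).to_csv(path / TABLE_FILES["process_map"], index=False)

    pd.DataFrame([{
        "unit_id": s.unit_id, "nurse_id": s.nurse_id,
        "annual_gross": s.annual_gross, "employment_fraction": s.employment_fraction,
        "active_from": str(s.active_from), "active_to": str(s.active_to),
    } for s in ledger.salaries]).to_csv(path / TABLE_FILES["salaries"], index=False)

    pd.DataFrame([{
        "unit_id": p.unit_id, "year": p.year, "hotel_daily": p.hotel_daily,
        **{c: p.nursing_level_revenue[i] for i, c in enumerate(_LEVEL_COLS)},
        "resident_nursing_share": p.resident_nursing_share,
        "regime": p.regime.kind, "reservation_fee": p.regime.reservation_fee,
        "daily_refund": p.regime.daily_refund,
    } for p in ledger.prices]).to_csv(path / TABLE_FILES["prices"], index=False)

    if ledger.episodes:
        pd.DataFrame([{
            "unit_id": ep.unit_id,
            "admission_date": ep.admission_date.isoformat(),
            "discharge_date": ep.discharge_date.isoformat(),
        } for ep in ledger.episodes]).to_csv(path / TABLE_FILES["episodes"], index=False)


def format_chf(value: float) -> str:
    """Two-decimal CHF presentation, rounding half away from zero."""
    d = decimal.Decimal(repr(value)).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    return f"{d:.2f}"
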