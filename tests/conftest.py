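import datetime

import pytest

import nhecon as nh
from nhecon.months import Month

# ---------------------------------------------------------------------------
# Published per-bed implementation cost/time breakdown used as a fixture.
# Category order: preparatory meetings, all-facility meeting, leadership
# meetings, nurse training, phone calls, internal training, administration
# (incl. coordination), travel, material.  Time has no material row.
# ---------------------------------------------------------------------------
IMPL_CATEGORIES = (
    "preparatory_leadership_meetings", "meeting_all_nhs", "leadership_icn_meetings",
    "icn_training", "phone_calls", "internal_training_events", "administration",
    "travel", "material",
)
IMPL_TIME_CATEGORIES = IMPL_CATEGORIES[:-1]

IMPL_COST_PER_BED = {
    "NH1": (56.51, 13.24, 59.32, 340.81, 31.46, 89.0, 196.97, 19.27, 0.0),
    "NH2": (12.55, 3.49, 21.36, 99.24, 10.38, 173.32, 217.75, 28.66, 2.35),
    "NH3": (45.27, 23.08, 89.88, 131.76, 21.62, 48.82, 72.41, 37.5, 0.0),
    "NH4": (39.41, 0.0, 45.55, 158.21, 24.81, 28.79, 64.34, 49.79, 0.0),
    "NH5": (19.96, 0.0, 27.02, 171.05, 13.16, 41.46, 266.89, 30.54, 48.97),
    "NH6": (68.47, 4.81, 39.38, 268.12, 19.25, 271.53, 67.0, 18.91, 35.17),
    "NH7": (14.07, 12.01, 31.68, 0.0, 26.08, 164.95, 339.03, 18.12, 27.78),
}
IMPL_TIME_PER_BED = {
    "NH1": (0.88, 0.19, 0.91, 7.03, 0.65, 1.84, 3.49, 0.31),
    "NH2": (0.21, 0.07, 0.4, 2.48, 0.26, 4.23, 3.56, 0.46),
    "NH3": (0.91, 0.38, 1.8, 1.2, 0.43, 0.98, 1.45, 1.07),
    "NH4": (0.75, 0.0, 0.89, 3.25, 0.53, 0.61, 1.3, 0.65),
    "NH5": (0.37, 0.0, 0.49, 3.42, 0.26, 0.75, 4.78, 1.16),
    "NH6": (1.31, 0.11, 0.72, 6.09, 0.44, 5.95, 1.31, 0.34),
    "NH7": (0.1, 0.12, 0.31, 0.0, 0.36, 0.8, 0.78, 1.38),
}
IMPL_TOTAL_COST = {"NH1": 806.57, "NH2": 569.1, "NH3": 470.34, "NH4": 410.89,
                   "NH5": 619.05, "NH6": 792.64, "NH7": 633.72}
IMPL_TOTAL_TIME = {"NH1": 15.3, "NH2": 11.67, "NH3": 8.22, "NH4": 7.98,
                   "NH5": 11.23, "NH6": 16.27, "NH7": 3.85}


def impl_entries(unit: str):
    """Per-bed cost and time rows as process-map entries (1-bed aggregation).

    Cost carried as a non-personnel amount and time as a wage-free
    1 x hours x 1 row, so each printed cell enters the aggregate verbatim.
    """
    entries = []
    for cat, cost in zip(IMPL_CATEGORIES, IMPL_COST_PER_BED[unit]):
        entries.append(nh.ProcessMapEntry(unit, cat, nonpersonnel_cost=cost))
    for cat, hours in zip(IMPL_TIME_CATEGORIES, IMPL_TIME_PER_BED[unit]):
        entries.append(nh.ProcessMapEntry(unit, cat, frequency=1.0,
                                          unit_duration=hours, participants=1.0))
    return entries


@pytest.fixture(scope="session")
def default_ledger():
    return nh.generate_ledger(nh.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_panel(default_ledger):
    panel, summary, result = nh.cea_from_ledger(default_ledger)
    return panel, summary, result


@pytest.fixture
def schedule():
    return nh.StudySchedule(
        preparatory_start=Month(2018, 4),
        baseline_start=Month(2018, 6),
        transition_start=Month(2018, 9),
        intervention_start=Month(2018, 10),
        intervention_end=Month(2019, 11),
    )


@pytest.fixture
def price_schedule():
    return nh.PriceSchedule(
        unit_id="NH1", year=2019, hotel_daily=150.0,
        nursing_level_revenue=tuple(float(10 * i) for i in range(1, 13)),
        resident_nursing_share=20.0,
        regime=nh.BillingRegime("B_hotel_continues"),
    )


def make_episode(unit="NH1", start=datetime.date(2019, 1, 10), nights=4):
    return nh.HospitalisationEpisode(unit, start, start + datetime.timedelta(days=nights))
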