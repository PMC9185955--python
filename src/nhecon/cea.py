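"""Cost-effectiveness analysis against usual (pre-intervention) care.

Effects and costs are indexed per facility per month:

* hospitalisation rate  = hospitalisations / nursing days x 1000
* salary rate           = nurse salary cost / nursing days x 1000 (CHF)

The comparator is pre-intervention usual care, whose incremental cost is
zero; cost and effect are same-year, so the discount rate is fixed at 0%.
The ICER is the mean intervention-period salary rate divided by the drop in
the mean hospitalisation rate (pre minus post), in CHF per avoided
hospitalisation.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable

from .intervention import SalaryRecord, monthly_salary_cost
from .ledger import Ledger
from .months import Month

#: Costs and effects accrue in the same year; read-only by convention.
DISCOUNT_RATE = 0.0

QUADRANTS = ("more_costly_more_effective", "dominant", "dominated",
             "less_costly_less_effective", "equivalent")


class CeaError(ValueError):
    pass


def hospitalisation_rate(hospitalisations: int, nursing_days: int) -> float:
    """Hospitalisations per 1000 nursing days."""
    if nursing_days <= 0:
        raise CeaError(f"nursing_days must be positive, got {nursing_days}")
    if hospitalisations < 0:
        raise CeaError("hospitalisations must be nonnegative")
    return hospitalisations / nursing_days * 1000.0


def salary_rate(salary_cost: float, nursing_days: int) -> float:
    """CHF of nurse salary per 1000 nursing days."""
    if nursing_days <= 0:
        raise CeaError(f"nursing_days must be positive, got {nursing_days}")
    if salary_cost < 0:
        raise CeaError("salary_cost must be nonnegative")
    return salary_cost / nursing_days * 1000.0


@dataclass(frozen=True)
class RateRow:
    """One facility-month of the rate panel.

    ``window`` is "pre" (all census months before the transition month —
    including the pre-study history supplied as comparator input), "post"
    (intervention months) or "transition".  The salary rate is zero in pre
    months because the comparator cost is zero.
    """

    unit_id: str
    month: Month
    window: str
    nursing_days: int
    hospitalisations: int
    hospitalisation_rate: float
    salary_cost: float
    salary_rate: float


def build_rate_panel(ledger: Ledger, include_transition: bool = False) -> list[RateRow]:
    """Derive the per-facility-month rate panel from the ledger.

    Months with zero nursing days are unusable in a rate and skipped.
    Transition months are excluded from both windows unless
    ``include_transition`` pools them into the intervention window.
    """
    salaries_by_unit: dict[str, list[SalaryRecord]] = {}
    for s in ledger.salaries:
        salaries_by_unit.setdefault(s.unit_id, []).append(s)

    rows: list[RateRow] = []
    for c in ledger.census:
        if c.nursing_days <= 0:
            continue
        sched = ledger.unit(c.unit_id).schedule
        if c.month < sched.transition_start:
            window = "pre"
        elif c.month < sched.intervention_start:
            window = "intervention" if include_transition else "transition"
        elif c.month <= sched.intervention_end:
            window = "post"
        else:
            continue
        if window == "transition":
            continue
        if window == "intervention":
            window = "post"
        cost = 0.0
        if window == "post":
            cost = sum(monthly_salary_cost(s)
                       for s in salaries_by_unit.get(c.unit_id, ())
                       if s.is_active(c.month))
        rows.append(RateRow(
            unit_id=c.unit_id, month=c.month, window=window,
            nursing_days=c.nursing_days, hospitalisations=c.hospitalisations,
            hospitalisation_rate=hospitalisation_rate(c.hospitalisations, c.nursing_days),
            salary_cost=cost,
            salary_rate=salary_rate(cost, c.nursing_days)))
    return rows


@dataclass(frozen=True)
class RateSummary:
    pre_rate_mean: float
    pre_rate_sd: float
    post_rate_mean: float
    post_rate_sd: float
    cost_mean: float      # mean intervention-period salary rate, CHF/1000 days
    cost_sd: float
    n_pre: int
    n_post: int


def _mean_sd(values: list[float]) -> tuple[float, float]:
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd


def summarise_rates(panel: Iterable[RateRow]) -> RateSummary:
    """Unweighted means and sample SDs over facility-month rows, by window."""
    panel = list(panel)
    pre = [r.hospitalisation_rate for r in panel if r.window == "pre"]
    post = [r.hospitalisation_rate for r in panel if r.window == "post"]
    cost = [r.salary_rate for r in panel if r.window == "post"]
    if not pre:
        raise CeaError("empty period: pre")
    if not post:
        raise CeaError("empty period: post")
    pre_m, pre_sd = _mean_sd(pre)
    post_m, post_sd = _mean_sd(post)
    cost_m, cost_sd = _mean_sd(cost)
    return RateSummary(pre_m, pre_sd, post_m, post_sd, cost_m, cost_sd,
                       len(pre), len(post))


@dataclass(frozen=True)
class CEAResult:
    incremental_cost: float       # CHF per 1000 nursing days
    incremental_effect: float     # avoided hospitalisations per 1000 nursing days
    icer: float                   # CHF per avoided hospitalisation (may be inf/negative)
    quadrant: str
    infinite: bool                # equal rates with nonzero cost
    dominated: bool               # positive cost, negative effect
    pre_rate_mean: float
    post_rate_mean: float
    discount_rate: float = DISCOUNT_RATE


def classify_quadrant(incremental_cost: float, incremental_effect: float) -> str:
    """Cost-effectiveness-plane quadrant of an (extra cost, extra effect) pair."""
    if incremental_cost == 0 and incremental_effect == 0:
        return "equivalent"
    if incremental_cost >= 0 and incremental_effect >= 0:
        return "more_costly_more_effective"
    if incremental_cost >= 0:
        return "dominated"
    if incremental_effect >= 0:
        return "dominant"
    return "less_costly_less_effective"


def icer(cost_mean: float, pre_rate_mean: float, post_rate_mean: float) -> CEAResult:
    """Incremental cost-effectiveness ratio against a zero-cost comparator.

    ``cost_mean / (pre_rate_mean - post_rate_mean)``.  A rate drop of zero
    with nonzero cost is an infinite ICER, signalled explicitly; a rate
    increase yields a negative ICER flagged as dominated rather than being
    silently returned as if favourable.
    """
    for name, v in (("cost_mean", cost_mean), ("pre_rate_mean", pre_rate_mean),
                    ("post_rate_mean", post_rate_mean)):
        if not math.isfinite(v):
            raise CeaError(f"{name} must be finite, got {v}")
    effect = pre_rate_mean - post_rate_mean
    infinite = effect == 0 and cost_mean != 0
    if effect == 0:
        value = math.inf if cost_mean > 0 else 0.0
    else:
        value = cost_mean / effect
    quadrant = classify_quadrant(cost_mean, effect)
    return CEAResult(
        incremental_cost=cost_mean, incremental_effect=effect, icer=value,
        quadrant=quadrant, infinite=infinite,
        dominated=(quadrant == "dominated"),
        pre_rate_mean=pre_rate_mean, post_rate_mean=post_rate_mean)


def cea_from_ledger(ledger: Ledger, include_transition: bool = False,
                    ) -> tuple[list[RateRow], RateSummary, CEAResult]:
    """End-to-end CEA: panel, summary statistics and ICER."""
    panel = build_rate_panel(ledger, include_transition=include_transition)
    summary = summarise_rates(panel)
    result = icer(summary.cost_mean, summary.pre_rate_mean, summary.post_rate_mean)
    return panel, summary, result
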