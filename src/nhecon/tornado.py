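"""One-way deterministic sensitivity analysis of the ICER with
tornado-diagram output.

One base-case input is perturbed at a time.  Count-like inputs (nursing
days, hospitalisation counts) move by a relative factor (default +/-20%)
applied uniformly to every facility-month of both windows; rate-like inputs
(salary rate, pre/post hospitalisation rate) are set to range endpoints
taken from the observed facility-month distribution.  A perturbation that
pushes the post rate above the pre rate is carried through as a negative
(dominated) ICER rather than truncated.

Uniform nursing-day scaling multiplies both rates and the salary rate by
the same factor, which cancels in the ICER — that row is null up to
floating-point rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .cea import CEAResult, RateRow, RateSummary, icer, summarise_rates

PARAMETERS = ("nursing_days", "n_hospitalisations", "salary_rate", "pre_rate", "post_rate")
RELATIVE_PARAMETERS = ("nursing_days", "n_hospitalisations")
RANGE_PARAMETERS = ("salary_rate", "pre_rate", "post_rate")

DEFAULT_RELATIVE_DELTA = 0.20


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivitySpec:
    """One parameter to perturb: relative +/-delta or explicit range ends."""

    parameter: str
    mode: str = "relative"          # "relative" | "range"
    low: float | None = None        # range mode endpoints
    high: float | None = None
    delta: float = DEFAULT_RELATIVE_DELTA

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise SensitivityError(f"unknown parameter: {self.parameter!r}")
        if self.mode not in ("relative", "range"):
            raise SensitivityError(f"unknown mode: {self.mode!r}")
        if self.mode == "range":
            if self.low is None or self.high is None:
                raise SensitivityError("range mode requires low and high endpoints")
            if self.low > self.high:
                raise SensitivityError("range endpoints inverted (low > high)")
        elif self.delta <= 0:
            raise SensitivityError("relative delta must be positive")


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    icer_low: float
    icer_high: float
    dominated_low: bool = False
    dominated_high: bool = False
    infinite_low: bool = False
    infinite_high: bool = False

    @property
    def bar_length(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class EvalRecord:
    """Audit entry proving the one-at-a-time guarantee."""

    parameter: str
    end: str          # "low" | "high"
    kind: str         # "factor" | "value"
    value: float


def _scaled_summary(panel: Sequence[RateRow], parameter: str, factor: float) -> RateSummary:
    """Recompute the summary after scaling one raw input in every row."""
    rows = []
    for r in panel:
        if parameter == "nursing_days":
            days = r.nursing_days * factor
            rows.append(replace(
                r,
                hospitalisation_rate=r.hospitalisations / days * 1000.0,
                salary_rate=r.salary_cost / days * 1000.0))
        else:  # n_hospitalisations
            rows.append(replace(
                r, hospitalisation_rate=(r.hospitalisations * factor) / r.nursing_days * 1000.0))
    return summarise_rates(rows)


def _icer_at(panel: Sequence[RateRow], base: RateSummary, spec: SensitivitySpec,
             end: str, log: list[EvalRecord] | None) -> CEAResult:
    if spec.mode == "relative":
        factor = 1.0 - spec.delta if end == "low" else 1.0 + spec.delta
        if log is not None:
            log.append(EvalRecord(spec.parameter, end, "factor", factor))
        s = _scaled_summary(panel, spec.parameter, factor)
        return icer(s.cost_mean, s.pre_rate_mean, s.post_rate_mean)
    value = spec.low if end == "low" else spec.high
    if log is not None:
        log.append(EvalRecord(spec.parameter, end, "value", value))
    cost, pre, post = base.cost_mean, base.pre_rate_mean, base.post_rate_mean
    if spec.parameter == "salary_rate":
        cost = value
    elif spec.parameter == "pre_rate":
        pre = value
    else:
        post = value
    return icer(cost, pre, post)


def observed_range(panel: Iterable[RateRow], parameter: str) -> tuple[float, float]:
    """Min/max of a rate over the relevant facility-month rows."""
    panel = list(panel)
    if parameter == "salary_rate":
        values = [r.salary_rate for r in panel if r.window == "post"]
    elif parameter == "pre_rate":
        values = [r.hospitalisation_rate for r in panel if r.window == "pre"]
    elif parameter == "post_rate":
        values = [r.hospitalisation_rate for r in panel if r.window == "post"]
    else:
        raise SensitivityError(f"no observed range for parameter {parameter!r}")
    if not values:
        raise SensitivityError(f"no rows to take a range from for {parameter!r}")
    return min(values), max(values)


def default_specs(panel: Iterable[RateRow]) -> list[SensitivitySpec]:
    """Base-case analysis plan: +/-20% on counts, sample ranges on rates."""
    panel = list(panel)
    specs = [SensitivitySpec(p, mode="relative") for p in RELATIVE_PARAMETERS]
    for p in RANGE_PARAMETERS:
        lo, hi = observed_range(panel, p)
        specs.append(SensitivitySpec(p, mode="range", low=lo, high=hi))
    return specs


def one_way(panel: Sequence[RateRow], base: RateSummary, spec: SensitivitySpec,
            log: list[EvalRecord] | None = None) -> TornadoRow:
    """Evaluate one sensitivity spec, perturbing exactly that parameter.

    Each end is a full re-evaluation of the ICER; dominated and infinite
    outcomes are flagged on the row and their (negative or infinite) values
    carried through unmodified.
    """
    lo = _icer_at(panel, base, spec, "low", log)
    hi = _icer_at(panel, base, spec, "high", log)
    return TornadoRow(
        parameter=spec.parameter,
        icer_low=lo.icer, icer_high=hi.icer,
        dominated_low=lo.dominated, dominated_high=hi.dominated,
        infinite_low=lo.infinite, infinite_high=hi.infinite)


def run_sensitivity(panel: Sequence[RateRow], base: RateSummary,
                    specs: Iterable[SensitivitySpec] | None = None,
                    log: list[EvalRecord] | None = None) -> list[TornadoRow]:
    if specs is None:
        specs = default_specs(panel)
    return tornado_order([one_way(panel, base, s, log) for s in specs])


def tornado_order(rows: Iterable[TornadoRow]) -> list[TornadoRow]:
    """Sort rows by bar length, longest first; ties break alphabetically."""
    def key(row: TornadoRow):
        length = row.bar_length
        if math.isnan(length):
            length = math.inf   # an unbounded end dominates the ordering
        return (-length, row.parameter)
    return sorted(rows, key=key)


def render_tornado(rows: Sequence[TornadoRow], base_icer: float, path) -> None:
    """Write the tornado diagram (SVG or PNG, by file extension).

    Horizontal bars span from the base-case ICER to each end's ICER; a
    vertical line marks the base case.  Output is deterministic for vector
    formats (fixed SVG hash salt, no embedded date).
    """
    rows = list(rows)
    if not rows:
        raise SensitivityError("no tornado rows to render")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with plt.rc_context({"svg.hashsalt": "nhecon"}):
        fig, ax = plt.subplots(figsize=(8, 0.9 * len(rows) + 1.5))
        labels = []
        for i, row in enumerate(reversed(rows)):   # longest bar on top
            lo = row.icer_low if math.isfinite(row.icer_low) else base_icer
            hi = row.icer_high if math.isfinite(row.icer_high) else base_icer
            left, width = min(lo, hi, base_icer), max(lo, hi, base_icer) - min(lo, hi, base_icer)
            ax.barh(i, width, left=left, height=0.6, color="#4878a8", edgecolor="black")
            labels.append(row.parameter)
        ax.axvline(base_icer, color="black", linewidth=1.2)
        ax.set_yticks(range(len(rows)), labels)
        ax.set_xlabel("CHF per avoided hospitalisation")
        ax.set_title("One-way sensitivity of the ICER")
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
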