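import math
import statistics

import pytest
from hypothesis import given
from hypothesis import strategies as st

import nhecon as nh
from nhecon.cea import CeaError, DISCOUNT_RATE
from nhecon.months import Month, month_range


class TestRates:
    def test_hospitalisation_rate(self):
        assert nh.hospitalisation_rate(4, 3200) == 1.25

    def test_zero_hospitalisations(self):
        assert nh.hospitalisation_rate(0, 3200) == 0.0

    def test_zero_days_rejected(self):
        with pytest.raises(CeaError):
            nh.hospitalisation_rate(1, 0)

    def test_salary_rate(self):
        assert nh.salary_rate(9000.0, 3000) == 3000.0

    def test_zero_salary(self):
        assert nh.salary_rate(0.0, 3000) == 0.0

    def test_salary_rate_zero_days_rejected(self):
        with pytest.raises(CeaError):
            nh.salary_rate(100.0, 0)


class TestSummariseRates:
    def make_panel(self, pre_rates, post_rates, cost_rates=None):
        rows = []
        for i, r in enumerate(pre_rates):
            rows.append(nh.RateRow("U", Month(2017, 1).add(i), "pre", 1000,
                                   round(r), r, 0.0, 0.0))
        cost_rates = cost_rates or [0.0] * len(post_rates)
        for i, (r, c) in enumerate(zip(post_rates, cost_rates)):
            rows.append(nh.RateRow("U", Month(2019, 1).add(i), "post", 1000,
                                   round(r), r, c, c))
        return rows

    def test_identical_rates_sd_zero(self):
        s = nh.summarise_rates(self.make_panel([1.1, 1.1, 1.1], [0.9, 0.9]))
        assert s.pre_rate_sd == 0.0 and s.post_rate_sd == 0.0

    def test_two_point_sample_statistics(self):
        s = nh.summarise_rates(self.make_panel([1.0, 1.5], [1.0, 1.5]))
        assert s.pre_rate_mean == pytest.approx(1.25)
        assert s.pre_rate_sd == pytest.approx(0.35355339, abs=1e-6)

    def test_empty_period_named(self):
        with pytest.raises(CeaError, match="pre"):
            nh.summarise_rates(self.make_panel([], [1.0]))
        with pytest.raises(CeaError, match="post"):
            nh.summarise_rates(self.make_panel([1.0], []))

    def test_generator_defaults_recover_rates(self, default_panel):
        _, summary, _ = default_panel
        assert summary.pre_rate_mean == pytest.approx(1.27, abs=0.2)
        assert summary.post_rate_mean == pytest.approx(1.14, abs=0.2)


class TestIcer:
    def test_base_case(self):
        res = nh.icer(2937.0, 1.27, 1.14)
        assert res.icer == pytest.approx(22592.3, abs=0.05)
        assert res.quadrant == "more_costly_more_effective"
        assert not res.dominated and not res.infinite

    def test_zero_cost(self):
        res = nh.icer(0.0, 1.27, 1.14)
        assert res.icer == 0.0

    def test_rate_increase_is_dominated(self):
        res = nh.icer(2937.0, 1.14, 1.27)
        assert res.icer < 0
        assert res.quadrant == "dominated" and res.dominated

    def test_equal_rates_signalled_infinite(self):
        res = nh.icer(2937.0, 1.2, 1.2)
        assert res.infinite and math.isinf(res.icer)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(CeaError):
            nh.icer(math.nan, 1.0, 0.9)

    def test_discount_rate_pinned_at_zero(self):
        assert DISCOUNT_RATE == 0.0
        assert nh.icer(1.0, 2.0, 1.0).discount_rate == 0.0


class TestClassifyQuadrant:
    @pytest.mark.parametrize("cost,effect,expected", [
        (2937.0, 0.13, "more_costly_more_effective"),
        (2937.0, -0.13, "dominated"),
        (-100.0, 0.13, "dominant"),
        (-100.0, -0.13, "less_costly_less_effective"),
        (0.0, 0.0, "equivalent"),
    ])
    def test_quadrants(self, cost, effect, expected):
        assert nh.classify_quadrant(cost, effect) == expected


@given(st.floats(1, 10_000), st.floats(0.01, 5), st.floats(0.01, 5))
def test_sign_coherence(cost, pre, post):
    """ICER > 0 iff incremental cost and effect share a sign; the quadrant
    label agrees with the signs."""
    res = nh.icer(cost, pre, post)
    if res.incremental_effect > 0:
        assert res.icer > 0 and res.quadrant == "more_costly_more_effective"
    elif res.incremental_effect < 0:
        assert res.icer < 0 and res.quadrant == "dominated"


@given(st.floats(0.1, 10))
def test_uniform_nursing_day_scaling_leaves_icer_unchanged(k):
    """Scaling every facility-month's nursing days by k scales both rates by
    1/k and cancels in the ICER (algebraic identity)."""
    counts = [(3, 2800), (5, 3100), (0, 2500), (4, 2900)]
    costs = [8000.0, 8200.0]
    post_counts = [(2, 2850), (3, 3050)]

    def icer_with(scale):
        pre = [h / (d * scale) * 1000 for h, d in counts]
        post = [h / (d * scale) * 1000 for h, d in post_counts]
        cost = [c / (d * scale) * 1000 for c, (_, d) in zip(costs, post_counts)]
        return nh.icer(statistics.fmean(cost), statistics.fmean(pre),
                       statistics.fmean(post)).icer
    assert icer_with(k) == pytest.approx(icer_with(1.0), rel=1e-9)


class TestBuildRatePanel:
    def test_pre_window_salary_rate_is_zero(self, default_panel):
        panel, _, _ = default_panel
        assert all(r.salary_rate == 0.0 for r in panel if r.window == "pre")

    def test_transition_excluded_by_default(self, default_ledger, default_panel):
        panel, _, _ = default_panel
        months = {(r.unit_id, r.month) for r in panel}
        for u in default_ledger.units:
            assert (u.unit_id, u.schedule.transition_start) not in months

    def test_include_transition_pools_into_post(self, default_ledger):
        panel = nh.build_rate_panel(default_ledger, include_transition=True)
        by_window = {}
        for r in panel:
            by_window.setdefault(r.window, 0)
            by_window[r.window] += 1
        base = nh.build_rate_panel(default_ledger)
        assert by_window["post"] == sum(1 for r in base if r.window == "post") + 7

    def test_pre_window_includes_pre_study_history(self, default_ledger):
        panel = nh.build_rate_panel(default_ledger)
        pre_months = [r.month for r in panel if r.window == "pre"]
        assert min(pre_months) == Month(2017, 1)


def test_oracle_equivalence_toy_panel():
    """Pipeline ICER on a 3-unit, 6-month ledger equals a brute-force
    recomputation from the raw counts, done without the panel code path."""
    from nhecon.ledger import Ledger, MonthlyCensus, NursingHomeUnit, StudySchedule

    sched = StudySchedule(Month(2018, 4), Month(2018, 6), Month(2018, 9),
                          Month(2018, 10), Month(2019, 9))
    units = [NursingHomeUnit(f"U{i}", 80 + 10 * i, sched) for i in range(3)]
    census, salaries = [], []
    raw = {
        "U0": [(2018, 6, 2400, 3), (2018, 7, 2450, 2), (2018, 8, 2400, 4),
               (2018, 10, 2400, 2), (2018, 11, 2350, 1), (2018, 12, 2400, 2)],
        "U1": [(2018, 6, 2700, 1), (2018, 7, 2750, 5), (2018, 8, 2700, 2),
               (2018, 10, 2700, 3), (2018, 11, 2650, 2), (2018, 12, 2700, 1)],
        "U2": [(2018, 6, 3000, 4), (2018, 7, 3100, 3), (2018, 8, 3000, 2),
               (2018, 10, 3000, 2), (2018, 11, 2950, 3), (2018, 12, 3000, 2)],
    }
    for uid, rows in raw.items():
        for y, m, d, h in rows:
            census.append(MonthlyCensus(uid, Month(y, m), d, h))
        salaries.append(nh.SalaryRecord(uid, f"{uid}-n", 84_000.0, 0.8,
                                        Month(2018, 10), Month(2019, 9)))
    ledger = Ledger(units=units, census=census, salaries=salaries)
    _, summary, result = nh.cea_from_ledger(ledger)

    # independent brute force over the raw dictionaries
    pre = [h / d * 1000 for rows in raw.values() for (y, m, d, h) in rows if (y, m) < (2018, 9)]
    post_rows = [(uid, d, h) for uid, rows in raw.items()
                 for (y, m, d, h) in rows if (y, m) >= (2018, 10)]
    post = [h / d * 1000 for _, d, h in post_rows]
    cost = [84_000.0 * 0.8 / 12 / d * 1000 for _, d, _ in post_rows]
    expected = (sum(cost) / len(cost)) / (sum(pre) / len(pre) - sum(post) / len(post))
    assert result.icer == pytest.approx(expected, rel=1e-12)
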