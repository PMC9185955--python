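import math

import numpy as np
import pytest

import nhecon as nh
from nhecon.months import Month
from nhecon.synth import (GeneratorConfig, GeneratorConfigError, _rng,
                          draw_monthly_hospitalisations, draw_salary,
                          generate_process_map)


class TestGeneratorConfig:
    def test_defaults_validate(self):
        GeneratorConfig()

    def test_inverted_range_rejected_before_any_draw(self):
        with pytest.raises(GeneratorConfigError, match="inverted"):
            GeneratorConfig(salary_range=(97_500.0, 68_738.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(pre_rate=-0.1)

    def test_occupancy_bounds(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(occupancy=0.0)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "gen.yaml"
        p.write_text("seed: 7\npre_rate: 1.5\nbeds_range: [70, 90]\n")
        cfg = GeneratorConfig.from_yaml(p)
        assert cfg.seed == 7 and cfg.pre_rate == 1.5 and cfg.beds_range == (70, 90)

    def test_yaml_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "gen.yaml"
        p.write_text("not_a_knob: 1\n")
        with pytest.raises(GeneratorConfigError, match="not_a_knob"):
            GeneratorConfig.from_yaml(p)


class TestGenerateLedger:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(seed=11)
        assert nh.generate_ledger(cfg) == nh.generate_ledger(cfg)

    def test_different_seeds_differ(self):
        assert nh.generate_ledger(GeneratorConfig(seed=1)) != \
            nh.generate_ledger(GeneratorConfig(seed=2))

    def test_zero_pre_rate_means_no_pre_hospitalisations(self):
        led = nh.generate_ledger(GeneratorConfig(seed=4, pre_rate=0.0))
        for c in led.census:
            sched = led.unit(c.unit_id).schedule
            if c.month < sched.transition_start:
                assert c.hospitalisations == 0

    def test_all_rows_pass_validation(self):
        for seed in (1, 2, 3):
            led = nh.generate_ledger(GeneratorConfig(seed=seed))
            assert nh.validate_ledger(led) == []

    def test_seven_units_one_group(self, default_ledger):
        assert len(default_ledger.units) == 7
        assert sum(1 for u in default_ledger.units if u.unit_id == "GRP") == 1

    def test_sequential_starts_one_or_two_per_month(self, default_ledger):
        starts = [u.schedule.intervention_start for u in default_ledger.units]
        counts = {m: starts.count(m) for m in starts}
        assert all(1 <= c <= 2 for c in counts.values())
        ordered = sorted(s.diff(Month(2018, 1)) for s in starts)
        assert ordered == sorted(ordered)
        assert min(starts) == Month(2018, 10)   # first transition Sept 2018

    def test_census_covers_17_pre_study_months(self, default_ledger):
        for u in default_ledger.units:
            months = [c.month for c in default_ledger.census if c.unit_id == u.unit_id]
            assert min(months) == Month(2017, 1)
            assert u.schedule.baseline_start.diff(min(months)) >= 17
            assert max(months) == u.schedule.intervention_end

    def test_all_tables_populated_per_unit(self, default_ledger):
        for u in default_ledger.units:
            assert any(e.unit_id == u.unit_id for e in default_ledger.process_map)
            assert any(s.unit_id == u.unit_id for s in default_ledger.salaries)
            assert any(p.unit_id == u.unit_id for p in default_ledger.prices)

    def test_pooled_pre_rate_recovers_config(self):
        """Monte-Carlo: pooled pre-intervention rate within 3 SE of 1.27."""
        rates = []
        for seed in range(1, 11):
            led = nh.generate_ledger(GeneratorConfig(seed=seed))
            _, summary, _ = nh.cea_from_ledger(led)
            rates.append(summary.pre_rate_mean)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / math.sqrt(len(rates))
        assert abs(rates.mean() - 1.27) <= 3 * se

    def test_named_substreams_are_stable(self):
        """Adding a later table's draws must not perturb earlier streams."""
        cfg = GeneratorConfig(seed=5)
        a = _rng(cfg, "census").random(4).tolist()
        _ = _rng(cfg, "prices").random(100)
        b = _rng(cfg, "census").random(4).tolist()
        assert a == b


class TestDrawMonthlyHospitalisations:
    def test_zero_rate(self):
        rng = np.random.default_rng(0)
        assert draw_monthly_hospitalisations(0.0, 5000, rng) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(GeneratorConfigError):
            draw_monthly_hospitalisations(-1.0, 100, np.random.default_rng(0))

    def test_poisson_mean(self):
        """Mean over 10'000 draws within 3 SE of 1.27 x 3000 / 1000 = 3.81."""
        rng = np.random.default_rng(123)
        draws = [draw_monthly_hospitalisations(1.27, 3000, rng) for _ in range(10_000)]
        se = math.sqrt(3.81 / 10_000)
        assert abs(np.mean(draws) - 3.81) <= 3 * se

    def test_overdispersion_keeps_mean(self):
        rng = np.random.default_rng(9)
        draws = [draw_monthly_hospitalisations(1.27, 3000, rng, overdispersion=2.0)
                 for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(3.81, rel=0.05)
        assert np.var(draws) > 1.5 * np.mean(draws)   # overdispersed


class TestDrawSalary:
    def test_within_printed_range(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            assert 68_738.0 <= draw_salary((68_738.0, 97_500.0), rng) <= 97_500.0

    def test_degenerate_interval(self):
        rng = np.random.default_rng(0)
        assert draw_salary((80_000.0, 80_000.0), rng) == 80_000.0

    def test_inverted_interval_rejected(self):
        with pytest.raises(GeneratorConfigError):
            draw_salary((2.0, 1.0), np.random.default_rng(0))

    def test_uniform_mean_is_midpoint(self):
        """Mean over 10'000 draws within 3 SE of the midpoint 83'119."""
        rng = np.random.default_rng(42)
        draws = [draw_salary((68_738.0, 97_500.0), rng) for _ in range(10_000)]
        width = 97_500.0 - 68_738.0
        se = width / math.sqrt(12) / math.sqrt(10_000)
        assert abs(np.mean(draws) - 83_119.0) <= 3 * se


class TestGenerateProcessMap:
    def make_unit(self, months=12):
        sched = nh.StudySchedule(Month(2018, 4), Month(2018, 6), Month(2018, 9),
                                 Month(2018, 10), Month(2018, 10).add(months - 1))
        return nh.NursingHomeUnit("U", 90, sched)

    def test_preparatory_meetings_offer_14_hours(self):
        entries = generate_process_map(self.make_unit(), GeneratorConfig(),
                                       np.random.default_rng(0))
        prep = [e for e in entries if e.category == "preparatory_leadership_meetings"]
        assert sum(e.frequency * e.unit_duration for e in prep) == 14.0  # 8+3+3

    def test_all_eight_personnel_categories_present(self):
        entries = generate_process_map(self.make_unit(), GeneratorConfig(),
                                       np.random.default_rng(0))
        cats = {e.category for e in entries}
        from nhecon.tdabc import NH_ORGANISED, NON_PERSONNEL, RESEARCH_ORGANISED
        assert cats == set(RESEARCH_ORGANISED) | set(NH_ORGANISED) | set(NON_PERSONNEL)

    def test_zero_intensity_drops_nh_organised_actions(self):
        cfg = GeneratorConfig(nh_action_intensity=0.0)
        entries = generate_process_map(self.make_unit(), cfg, np.random.default_rng(0))
        cats = {e.category for e in entries}
        assert not cats & {"internal_training_events", "administration",
                           "internal_coordination"}

    def test_phone_calls_scale_with_intervention_length(self):
        """Twice-monthly one-hour calls: a 17-month unit accrues more call
        time than a 12-month unit."""
        def call_hours(months):
            entries = generate_process_map(self.make_unit(months), GeneratorConfig(),
                                           np.random.default_rng(0))
            calls = [e for e in entries if e.category == "phone_calls"]
            return sum(e.frequency * e.unit_duration for e in calls)
        assert call_hours(17) == call_hours(12) + 2 * 5  # 2 calls/month extra
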