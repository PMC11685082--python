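"""Costing, utilities, discounting, ICER and NMB arithmetic."""

import numpy as np
import pytest

from sclccea.econ import (AdverseEvent, CEResult, DiscountRates, StrategyEconomics,
                          SubsequentMix, accumulate, discount_factor,
                          followup_interval_days, icer, nmb)
from sclccea.markov_core import ModelClock, TransitionRow, run_cohort
from sclccea.pipeline import build_strategy_economics

NO_DISCOUNT = DiscountRates(cost=0.0, qaly=0.0)


def even_mix():
    return SubsequentMix(0.2, 0.2, 0.2, 0.2, 0.2)


def toy_strategy(**kw):
    defaults = dict(
        name="toy", ec_cost_per_cycle=0.0, continuous_cost_per_cycle=0.0,
        ec_n_cycles=0, subsequent_mix=even_mix(),
        subsequent_costs={"radiotherapy": 0.0, "chemotherapy": 0.0, "targeted": 0.0,
                          "immunotherapy": 0.0, "best_supportive": 0.0},
        adverse_events=[], followup_visit_cost=0.0, end_of_life_cost=0.0,
        u_pfs=0.84, u_pd=0.473, uplift_rate=0.0,
    )
    defaults.update(kw)
    return StrategyEconomics(**defaults)


def clock_of(n_cycles):
    return ModelClock(horizon_years=n_cycles * 21 / 365.25)


def stay_in_pfs(n_cycles):
    clock = clock_of(n_cycles)
    rows = [TransitionRow(t, 1.0, 0.0, 0.0, 1.0, 0.0) for t in range(clock.n_cycles)]
    return run_cohort(rows, clock), clock


class TestDiscountFactor:
    def test_time_zero(self):
        assert discount_factor(0.0, 0.05) == 1.0

    def test_zero_rate(self):
        assert discount_factor(987.0, 0.0) == 1.0

    def test_one_year_at_five_percent(self):
        assert discount_factor(365.25, 0.05) == pytest.approx(0.952381, abs=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(10.0, -0.01)


def test_followup_schedule_intervals():
    month = 365.25 / 12
    assert followup_interval_days(100.0) == pytest.approx(2 * month)
    assert followup_interval_days(2 * 365.25) == pytest.approx(3 * month)
    assert followup_interval_days(4 * 365.25) == pytest.approx(6 * month)
    assert followup_interval_days(8 * 365.25) == pytest.approx(365.25)


class TestAccumulate:
    def test_one_cycle_drug_cost(self):
        # benmelstobart + anlotinib for one undiscounted cycle in PFS
        trace, clock = stay_in_pfs(1)
        s = toy_strategy(continuous_cost_per_cycle=3444.60 + 403.46)
        r = accumulate(trace, s, clock, NO_DISCOUNT)
        assert r.cost_pfs_drugs == pytest.approx(3848.06)

    def test_one_cycle_qaly(self):
        trace, clock = stay_in_pfs(1)
        r = accumulate(trace, toy_strategy(), clock, NO_DISCOUNT)
        assert r.total_qalys == pytest.approx(0.84 * 21 / 365.25, abs=1e-6)
        assert r.total_qalys == pytest.approx(0.048296, abs=1e-6)

    def test_ec_backbone_stops_after_four_cycles(self):
        s = toy_strategy(ec_cost_per_cycle=391.54, ec_n_cycles=4)
        t4, c4 = stay_in_pfs(4)
        t6, c6 = stay_in_pfs(6)
        r4 = accumulate(t4, s, c4, NO_DISCOUNT)
        r6 = accumulate(t6, s, c6, NO_DISCOUNT)
        # cycles 5 and 6 add no EC cost
        assert r6.cost_pfs_drugs == pytest.approx(r4.cost_pfs_drugs)
        assert r4.cost_pfs_drugs == pytest.approx(4 * 391.54)

    def test_all_dead_trace_zeroes(self):
        clock = clock_of(2)
        rows = [TransitionRow(t, 0.0, 0.0, 1.0, 0.0, 1.0) for t in range(2)]
        trace = run_cohort(rows, clock)
        trace.pfs[:], trace.death[:] = 0.0, 1.0  # dead from the very start
        trace.new_deaths[:] = 0.0
        r = accumulate(trace, toy_strategy(), clock, NO_DISCOUNT)
        assert r.total_qalys == 0.0
        assert r.cost_pfs_drugs == 0.0

    def test_breakdown_sums_to_total(self):
        clock = clock_of(30)
        rows = [TransitionRow(t, 0.9, 0.07, 0.03, 0.92, 0.08) for t in range(30)]
        trace = run_cohort(rows, clock)
        s = toy_strategy(
            continuous_cost_per_cycle=100.0, ec_cost_per_cycle=50.0, ec_n_cycles=4,
            subsequent_costs={"radiotherapy": 26.33, "chemotherapy": 77.36,
                              "targeted": 403.46, "immunotherapy": 5026.09,
                              "best_supportive": 332.85},
            adverse_events=[AdverseEvent("ae", 0.5, 300.0, -0.1)],
            followup_visit_cost=567.61, end_of_life_cost=7985.90)
        r = accumulate(trace, s, clock, DiscountRates())
        assert sum(r.breakdown().values()) == pytest.approx(r.total_cost_usd, abs=1e-6)
        assert r.total_qalys <= r.total_life_years

    def test_two_cycle_brute_force(self):
        """Totals match a hand enumeration for a constant 2-cycle chain."""
        clock = clock_of(2)
        r0 = TransitionRow(0, 0.7, 0.2, 0.1, 0.8, 0.2)
        trace = run_cohort([r0, r0], clock)
        s = toy_strategy(continuous_cost_per_cycle=100.0,
                         subsequent_costs={"radiotherapy": 0, "chemotherapy": 0,
                                           "targeted": 0, "immunotherapy": 50.0,
                                           "best_supportive": 0},
                         end_of_life_cost=1000.0)
        res = accumulate(trace, s, clock, NO_DISCOUNT)
        # membership: pfs 1, .7, .49 ; pd 0, .2, .3 ; new deaths .1, .11
        pfs_bar = [(1 + 0.7) / 2, (0.7 + 0.49) / 2]
        pd_bar = [0.1, 0.25]
        cost_pfs = 100.0 * sum(pfs_bar)
        cost_pd = 0.2 * 50.0 * sum(pd_bar)  # immunotherapy share only
        cost_eol = 1000.0 * (0.1 + 0.11)
        assert res.cost_pfs_drugs == pytest.approx(cost_pfs)
        assert res.cost_pd_drugs == pytest.approx(cost_pd)
        assert res.cost_end_of_life == pytest.approx(cost_eol)
        cyc_y = 21 / 365.25
        qalys = sum(0.84 * m * cyc_y for m in pfs_bar) + sum(
            0.473 * m * cyc_y for m in pd_bar)
        assert res.total_qalys == pytest.approx(qalys)

    def test_immunotherapy_cap_switches_to_bsc(self):
        n = 10
        clock = clock_of(n)
        rows = [TransitionRow(0, 0.0, 1.0, 0.0, 1.0, 0.0)] + [
            TransitionRow(t, 1.0, 0.0, 0.0, 1.0, 0.0) for t in range(1, n)]
        trace = run_cohort(rows, clock)  # everyone progresses at cycle 1
        s = toy_strategy(
            subsequent_mix=SubsequentMix(0, 0, 0, 1.0, 0),
            subsequent_costs={"radiotherapy": 0, "chemotherapy": 0, "targeted": 0,
                              "immunotherapy": 1000.0, "best_supportive": 10.0},
            immunotherapy_cap_cycles=3)
        r = accumulate(trace, s, clock, NO_DISCOUNT)
        # compartments 0,1,2 pay 1000; beyond pays 10 (half-cycle smears entry)
        capped = accumulate(trace, toy_strategy(
            subsequent_mix=SubsequentMix(0, 0, 0, 1.0, 0),
            subsequent_costs={"radiotherapy": 0, "chemotherapy": 0, "targeted": 0,
                              "immunotherapy": 1000.0, "best_supportive": 10.0},
            immunotherapy_cap_cycles=n + 2), clock, NO_DISCOUNT)
        assert r.cost_pd_drugs < capped.cost_pd_drugs

    def test_uplift_raises_qalys_before_cutoff_only(self):
        trace, clock = stay_in_pfs(40)  # 40 cycles ~ 2.3 years
        base = accumulate(trace, toy_strategy(), clock, NO_DISCOUNT)
        up = accumulate(trace, toy_strategy(uplift_rate=0.05), clock, NO_DISCOUNT)
        cyc_y = 21 / 365.25
        cutoff_cycles = sum(((t + 0.5) * 21 / 365.25) <= 2.0 for t in range(40))
        expected_gain = 0.84 * 0.05 * cyc_y * cutoff_cycles
        assert up.total_qalys - base.total_qalys == pytest.approx(expected_gain, rel=1e-9)

    def test_discounting_reduces_totals(self):
        clock = clock_of(50)
        rows = [TransitionRow(t, 0.95, 0.03, 0.02, 0.95, 0.05) for t in range(50)]
        trace = run_cohort(rows, clock)
        s = toy_strategy(continuous_cost_per_cycle=100.0,
                         end_of_life_cost=500.0, followup_visit_cost=50.0)
        undisc = accumulate(trace, s, clock, NO_DISCOUNT)
        disc = accumulate(trace, s, clock, DiscountRates(0.05, 0.05))
        assert disc.total_cost_usd < undisc.total_cost_usd
        assert disc.total_qalys < undisc.total_qalys

    def test_cost_and_utility_monotonicity(self):
        clock = clock_of(20)
        rows = [TransitionRow(t, 0.9, 0.07, 0.03, 0.9, 0.1) for t in range(20)]
        trace = run_cohort(rows, clock)
        lo = accumulate(trace, toy_strategy(continuous_cost_per_cycle=100.0),
                        clock, NO_DISCOUNT)
        hi = accumulate(trace, toy_strategy(continuous_cost_per_cycle=150.0),
                        clock, NO_DISCOUNT)
        assert hi.total_cost_usd >= lo.total_cost_usd
        u_lo = accumulate(trace, toy_strategy(u_pd=0.40), clock, NO_DISCOUNT)
        u_hi = accumulate(trace, toy_strategy(u_pd=0.50), clock, NO_DISCOUNT)
        assert u_hi.total_qalys >= u_lo.total_qalys


class TestICER:
    @staticmethod
    def result(name, cost, qalys):
        return CEResult(name, cost, qalys, qalys, 0, 0, 0, 0, 0)

    def test_dominant_flag(self):
        c = icer(self.result("a", 95.0, 1.2), self.result("b", 100.0, 1.0))
        assert c.dominant and not c.dominated

    def test_dominated_flag(self):
        c = icer(self.result("a", 105.0, 0.9), self.result("b", 100.0, 1.0))
        assert c.dominated

    def test_undefined_when_equal_qalys(self):
        c = icer(self.result("a", 105.0, 1.0), self.result("b", 100.0, 1.0))
        assert c.icer is None


class TestNMB:
    def test_zero_wtp(self):
        r = TestICER.result("a", 500.0, 1.0)
        assert nmb(r, 0.0) == -500.0

    def test_zero_cost(self):
        r = TestICER.result("a", 0.0, 2.0)
        assert nmb(r, 37_598.0) == pytest.approx(75_196.0)

    def test_break_even(self):
        r = TestICER.result("a", 37_598.0, 1.0)
        assert nmb(r, 37_598.0) == pytest.approx(0.0)


class TestAEBlockAgainstPrintedTotals:
    """The undiscounted one-off AE cost equals incidence x cost summed over
    the arm's event list; the printed per-arm totals agree within 0.5%
    (the residual is the source table's own rounding)."""

    @pytest.mark.parametrize("arm,printed", [
        ("benmel_anlo_ec", 919.91), ("anlo_ec", 948.80), ("ec", 723.75)])
    def test_ae_cost_total(self, default_config, arm, printed):
        strategies = build_strategy_economics(default_config)
        assert strategies[arm].ae_cost_total() == pytest.approx(printed, rel=0.005)
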