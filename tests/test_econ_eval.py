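"""Discounting, accumulation, wages, frontier and net monetary benefit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afecon.econ_eval import (
    StateValues,
    StrategyOutcome,
    WageParams,
    accumulate,
    discount_factor,
    icer_frontier,
    indirect_cost,
    monthly_wage_usd,
    nmb,
    ppp_convert,
)
from afecon.errors import InvalidParameterError, SchemaError
from afecon.fixtures import make_toy_model
from afecon.model_core import CohortTrace, ModelConfig, run_cohort


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate, t, expected",
        [(0.0, 5.0, 1.0), (0.072, 1.0, 0.932836), (0.03, 10.0, 0.744094)],
    )
    def test_known_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=5e-7)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidParameterError):
            discount_factor(0.03, -1.0)


class TestAccumulate:
    def test_full_health_one_year_is_one_qaly(self):
        toy = make_toy_model(
            n_states=2, death_prob=0.0, utility=1.0, n_cycles=12, cycle_length=1 / 12
        )
        trace = run_cohort(toy["matrix"], toy["init"], 12, cycle_length=1 / 12)
        out = accumulate(trace, toy["values"], toy["config"])
        assert out.total_qaly == pytest.approx(1.0, rel=1e-12)

    def test_zero_costs_give_zero_total(self):
        toy = make_toy_model(n_states=2, death_prob=0.2, cost=0.0, n_cycles=10)
        trace = run_cohort(toy["matrix"], toy["init"], 10, cycle_length=1.0)
        assert accumulate(trace, toy["values"], toy["config"]).total_cost == 0.0

    @pytest.mark.parametrize("discount", [0.0, 0.072])
    def test_matches_geometric_closed_form(self, discount):
        toy = make_toy_model(
            n_states=2, death_prob=0.1, cost=50.0, utility=0.8, n_cycles=24,
            cycle_length=1 / 12, discount_cost=discount, discount_effect=discount,
        )
        trace = run_cohort(toy["matrix"], toy["init"], 24, cycle_length=1 / 12)
        out = accumulate(trace, toy["values"], toy["config"])
        assert out.total_cost == pytest.approx(toy["analytic"]["cost_per_patient"], rel=1e-10)
        assert out.total_qaly == pytest.approx(toy["analytic"]["qaly_per_patient"], rel=1e-10)

    def test_undiscounted_ten_cycle_survival_qaly(self):
        # frozen geometric sum: sum_{t=0..9} 0.9^t = 6.5132156
        toy = make_toy_model(n_states=2, death_prob=0.1, utility=1.0, n_cycles=10)
        trace = run_cohort(toy["matrix"], toy["init"], 10, cycle_length=1.0)
        out = accumulate(trace, toy["values"], toy["config"])
        assert out.total_qaly == pytest.approx(6.5132156, abs=1e-6)

    def test_state_mismatch_raises(self):
        toy = make_toy_model(n_states=2)
        trace = run_cohort(toy["matrix"], toy["init"], 3, cycle_length=1.0)
        bad = StateValues(
            dmc={"X": 0.0}, dnmc={"X": 0.0}, ic={"X": 0.0},
            utility={"X": 1.0}, event_cost={"X": 0.0},
        )
        with pytest.raises(SchemaError):
            accumulate(trace, bad, toy["config"])

    def test_half_cycle_correction_averages_occupancy(self):
        toy = make_toy_model(n_states=2, death_prob=0.5, utility=1.0, n_cycles=1)
        trace = run_cohort(toy["matrix"], toy["init"], 1, cycle_length=1.0)
        cfg_on = toy["config"].replace(half_cycle_correction=True)
        out_off = accumulate(trace, toy["values"], toy["config"])
        out_on = accumulate(trace, toy["values"], cfg_on)
        assert out_off.total_qaly == pytest.approx(1.0)
        assert out_on.total_qaly == pytest.approx(0.75)


class TestWageArithmetic:
    def test_printed_wage_conversions(self):
        w = WageParams()
        assert indirect_cost(w, 1.0) == pytest.approx(4.32, abs=0.005)
        assert monthly_wage_usd(w) == pytest.approx(129.52, abs=0.005)
        assert indirect_cost(w, 0.0) == 0.0

    def test_ppp_threshold(self):
        assert ppp_convert(700e6, 62_870) == pytest.approx(11134, abs=0.5)

    def test_negative_days_rejected(self):
        with pytest.raises(InvalidParameterError):
            indirect_cost(WageParams(), -1.0)


# QALYs recovered from printed total cost / ACER pairs
_RIVA = StrategyOutcome("rivaroxaban", 109.99, 109.99 / 827.197)
_APIX = StrategyOutcome("apixaban", 126.18, 126.18 / 937.448)
_WARF = StrategyOutcome("vka", 150.49, 150.49 / 1293.331)


class TestFrontier:
    def test_published_base_case_structure(self):
        entries = {e.strategy: e for e in icer_frontier([_RIVA, _APIX, _WARF])}
        assert entries["vka"].dominance == "absolutely_dominated"
        assert entries["rivaroxaban"].dominance == "undominated"
        assert entries["apixaban"].dominance == "undominated"
        # apixaban vs rivaroxaban ICER ~ 9.9e3 per QALY
        assert entries["apixaban"].icer == pytest.approx(9918.2, abs=1.0)
        # warfarin referenced against apixaban: negative ICER (dominated)
        assert entries["vka"].icer == pytest.approx(-1332.7, abs=0.5)
        assert entries["rivaroxaban"].icer is None

    def test_strict_dominance_both_axes(self):
        a = StrategyOutcome("a", 100.0, 1.0)
        b = StrategyOutcome("b", 50.0, 2.0)
        entries = {e.strategy: e for e in icer_frontier([a, b])}
        assert entries["a"].dominance == "absolutely_dominated"
        assert entries["b"].dominance == "undominated"

    def test_identical_outcomes_tie(self):
        a = StrategyOutcome("a", 100.0, 1.0)
        b = StrategyOutcome("b", 100.0, 1.0)
        entries = icer_frontier([a, b])
        assert all(e.dominance == "undominated" for e in entries)
        assert entries[1].icer is None

    def test_extended_dominance_removed(self):
        # middle strategy has a higher ICER than the step beyond it
        a = StrategyOutcome("cheap", 0.0, 0.0)
        b = StrategyOutcome("mid", 100.0, 0.001)
        c = StrategyOutcome("rich", 110.0, 0.01)
        entries = {e.strategy: e for e in icer_frontier([a, b, c])}
        assert entries["mid"].dominance == "extendedly_dominated"
        assert entries["rich"].icer == pytest.approx(110.0 / 0.01, rel=1e-9)

    def test_acer_consistency_invariant(self):
        for e in icer_frontier([_RIVA, _APIX, _WARF]):
            assert e.acer * e.total_qaly == pytest.approx(e.total_cost, rel=1e-9)

    def test_frontier_icers_strictly_increase(self):
        outs = [
            StrategyOutcome("s0", 0.0, 0.0),
            StrategyOutcome("s1", 10.0, 1.0),
            StrategyOutcome("s2", 30.0, 2.0),
            StrategyOutcome("s3", 70.0, 3.0),
        ]
        chain = [e for e in icer_frontier(outs) if e.dominance == "undominated"]
        icers = [e.icer for e in chain if e.icer is not None]
        assert icers == sorted(icers)
        assert all(x < y for x, y in zip(icers, icers[1:]))


class TestNMB:
    def test_printed_value(self):
        assert nmb(StrategyOutcome("apixaban", 126.18, 0.1346), 11134) == pytest.approx(
            1372.46, abs=0.01
        )

    def test_zero_threshold_is_negative_cost(self):
        o = StrategyOutcome("x", 42.0, 1.0)
        assert nmb(o, 0.0) == -42.0

    @given(
        lam=st.floats(0, 1e5),
        shift=st.floats(0, 1e4),
        q=st.tuples(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.1, 10)),
        c=st.tuples(st.floats(0, 1e4), st.floats(0, 1e4), st.floats(0, 1e4)),
    )
    @settings(max_examples=100)
    def test_ranking_invariant_to_constant_cost(self, lam, shift, q, c):
        outs = [StrategyOutcome(f"s{i}", c[i], q[i]) for i in range(3)]
        shifted = [StrategyOutcome(f"s{i}", c[i] + shift, q[i]) for i in range(3)]
        rank = sorted(range(3), key=lambda i: nmb(outs[i], lam))
        rank2 = sorted(range(3), key=lambda i: nmb(shifted[i], lam))
        assert rank == rank2
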