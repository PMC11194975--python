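"""Cohort Markov engine: conversions, matrices, traces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afecon.analysis import StrategyEngine, evaluate_strategy
from afecon.errors import (
    DegenerateParameterError,
    InvalidParameterError,
    SchemaError,
)
from afecon.fixtures import default_aux_params, make_toy_model
from afecon.model_core import (
    EventRate,
    LifeTable,
    ModelConfig,
    TransitionMatrix,
    build_transition_matrix,
    rate_to_cycle_prob,
    run_cohort,
)
from afecon.states import EVENTS, STATE_ORDER


class TestRateToCycleProb:
    @pytest.mark.parametrize(
        "rate, cycle, expected",
        [
            # monthly conversion of the apixaban ischemic-stroke rate
            (0.950, 1 / 12, 7.913534e-4),
            (0.0, 1 / 12, 0.0),
            (2.995, 1 / 12, 1 - math.exp(-0.02995 / 12)),
        ],
    )
    def test_known_values(self, rate, cycle, expected):
        assert rate_to_cycle_prob(rate, cycle) == pytest.approx(expected, rel=1e-6)

    def test_saturates_at_one(self):
        assert rate_to_cycle_prob(1e6, 1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rate, cycle", [(-0.1, 1.0), (1.0, 0.0), (1.0, -1.0)])
    def test_domain_errors(self, rate, cycle):
        with pytest.raises(InvalidParameterError):
            rate_to_cycle_prob(rate, cycle)

    @given(rate=st.floats(0, 500), cycle=st.floats(1e-3, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_is_probability_and_monotone(self, rate, cycle):
        p = rate_to_cycle_prob(rate, cycle)
        assert 0.0 <= p < 1.0
        assert rate_to_cycle_prob(rate + 1.0, cycle) >= p


class TestEventRate:
    def test_ci_must_bracket_nonnegative(self):
        with pytest.raises(InvalidParameterError):
            EventRate(1.0, 2.0, 0.5).validate()
        with pytest.raises(InvalidParameterError):
            EventRate(-1.0, 0.0, 1.0).validate()

    def test_mean_outside_ci_warns_not_raises(self):
        # published tables occasionally print this; must load verbatim
        with pytest.warns(UserWarning):
            EventRate(0.582, 0.612, 1.176).validate("vka/ich")


class TestLifeTable:
    def test_floor_lookup_and_constant_extrapolation(self):
        lt = LifeTable([50, 51, 52], [0.01, 0.02, 0.03])
        assert lt.annual_prob(50.9) == 0.01
        assert lt.annual_prob(51.0) == 0.02
        assert lt.annual_prob(30.0) == 0.01
        assert lt.annual_prob(120.0) == 0.03


class TestBuildTransitionMatrix:
    def test_zero_rates_zero_mortality_is_identity_on_af(self):
        aux = default_aux_params()
        import dataclasses

        aux = dataclasses.replace(
            aux,
            discontinuation_rate_per_100py=0.0,
            untreated_rates={e: 0.0 for e in EVENTS},
            life_table=LifeTable([0], [0.0]),
        )
        rates = {e: 0.0 for e in EVENTS}
        m = build_transition_matrix(rates, aux, 50.0, ModelConfig())
        i_af = STATE_ORDER.index("AF")
        assert m.array[i_af, i_af] == 1.0

    def test_af_self_loop_is_one_minus_event_probabilities(self, bundle):
        import dataclasses

        aux = dataclasses.replace(
            bundle.aux,
            discontinuation_rate_per_100py=0.0,
            life_table=LifeTable([0], [0.0]),
        )
        cfg = ModelConfig()
        rates = bundle.rates.rates_for("apixaban")
        m = build_transition_matrix(rates, aux, 50.0, cfg)
        expected = 1.0 - sum(rate_to_cycle_prob(rates[e], cfg.cycle_length) for e in EVENTS)
        assert m.array[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_rows_sum_to_one_for_all_strategies_and_ages(self, bundle):
        for strategy in bundle.strategies:
            rates = bundle.rates.rates_for(strategy)
            for age in (50, 65, 80, 105):
                m = build_transition_matrix(rates, bundle.aux, age, bundle.config)
                np.testing.assert_allclose(m.array.sum(axis=1), 1.0, atol=1e-10)

    def test_dead_row_is_identity(self, bundle):
        m = build_transition_matrix(
            bundle.rates.rates_for("vka"), bundle.aux, 60, bundle.config
        )
        i_dead = STATE_ORDER.index("DEAD")
        row = np.zeros(len(STATE_ORDER))
        row[i_dead] = 1.0
        np.testing.assert_array_equal(m.array[i_dead], row)

    def test_overfull_row_raises_with_state_name(self, bundle):
        # absurd rates at a yearly cycle over-fill the AF row
        rates = {e: 5000.0 for e in EVENTS}
        cfg = ModelConfig(cycle_length=1.0, horizon=5)
        with pytest.raises(DegenerateParameterError) as exc:
            build_transition_matrix(rates, bundle.aux, 50, cfg)
        assert "AF" in str(exc.value)

    @given(bump=st.sampled_from(EVENTS), delta=st.floats(0.1, 20.0))
    @settings(max_examples=40, deadline=None)
    def test_increasing_a_rate_never_increases_self_loop(self, bundle, bump, delta):
        rates = bundle.rates.rates_for("apixaban")
        m0 = build_transition_matrix(rates, bundle.aux, 55, bundle.config)
        rates2 = dict(rates)
        rates2[bump] += delta
        m1 = build_transition_matrix(rates2, bundle.aux, 55, bundle.config)
        assert m1.array[0, 0] <= m0.array[0, 0]


class TestRunCohort:
    def test_two_state_geometric_survival(self):
        toy = make_toy_model(n_states=2, death_prob=0.1, n_cycles=20)
        trace = run_cohort(toy["matrix"], toy["init"], 20, cycle_length=1.0)
        alive = trace.occupancy[:, 0]
        expected = 1000.0 * 0.9 ** np.arange(21)
        np.testing.assert_allclose(alive, expected, rtol=1e-10)

    def test_three_state_matches_matrix_power(self):
        toy = make_toy_model(n_states=3, death_prob=0.07, n_cycles=30)
        trace = run_cohort(toy["matrix"], toy["init"], 30, cycle_length=1.0)
        # independent oracle: direct matrix power
        for t in (1, 7, 30):
            expected = toy["init"] @ np.linalg.matrix_power(toy["matrix"].array, t)
            np.testing.assert_allclose(trace.occupancy[t], expected, rtol=1e-10)

    def test_identity_matrix_keeps_trace_constant(self):
        m = TransitionMatrix(["A", "B"], np.eye(2))
        trace = run_cohort(m, [600.0, 400.0], 5)
        assert (trace.occupancy == [600.0, 400.0]).all()

    def test_cycle_count_shape(self, bundle):
        eng = StrategyEngine(bundle, "apixaban")
        trace = eng.trace()
        # 30-year horizon at monthly cycles: 360 transitions + initial row
        assert trace.occupancy.shape[0] == 361

    def test_conservation_and_monotone_dead(self, bundle):
        trace = StrategyEngine(bundle, "vka").trace()
        trace.check_conservation()
        dead = trace.occupancy[:, STATE_ORDER.index("DEAD")]
        assert (np.diff(dead) >= -1e-9).all()

    def test_dimension_mismatch_raises(self):
        m = TransitionMatrix(["A", "B"], np.eye(2))
        with pytest.raises(SchemaError):
            run_cohort(m, [1.0, 2.0, 3.0], 4)

    def test_too_few_matrices_raises(self):
        m = TransitionMatrix(["A", "B"], np.eye(2))
        with pytest.raises(InvalidParameterError):
            run_cohort([m, m], [1.0, 0.0], 5)


def test_engine_matches_public_build_and_run(bundle):
    """The fast engine and the step-by-step public API agree."""
    from afecon.econ_eval import accumulate

    eng = StrategyEngine(bundle, "rivaroxaban")
    out_engine = eng.evaluate()

    cfg = bundle.config
    rates = bundle.rates.rates_for("rivaroxaban")
    n = cfg.n_cycles
    mats = []
    for t in range(n):
        age = cfg.start_age + t * cfg.cycle_length
        mats.append(build_transition_matrix(rates, bundle.aux, age, cfg))
    init = np.zeros(len(STATE_ORDER))
    init[0] = cfg.cohort_size
    trace = run_cohort(mats, init, n, cycle_length=cfg.cycle_length)
    out_public = accumulate(trace, bundle.values["rivaroxaban"], cfg)
    assert out_public.total_cost == pytest.approx(out_engine.total_cost, rel=1e-12)
    assert out_public.total_qaly == pytest.approx(out_engine.total_qaly, rel=1e-12)
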