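"""Model bundle, canonical evaluation path, and the base-case analysis.

A :class:`ModelBundle` holds everything needed to evaluate one decision
problem: the per-strategy event-rate table, per-strategy state values,
auxiliary clinical parameters and the model configuration. Every analysis
(base case, DSA, PSA) evaluates strategies through the same numeric
engine, so a probabilistic iteration with point-mass distributions
reproduces the base case bit-for-bit.

Parameters are addressable by string id for sensitivity analyses:

=======================  ===========  =====================================
id pattern               category     meaning
=======================  ===========  =====================================
``rate:<strategy>:<ev>``  probability  on-treatment event rate per 100 PY
``untreated_rate:<ev>``   probability  off-treatment event rate per 100 PY
``disc_rate``             probability  discontinuation rate per 100 PY
``fatality:<ev>``         probability  case-fatality fraction of event
``treatment_cost:<s>``    cost         per-cycle cost of the AF state
``state_cost:<state>``    cost         per-cycle cost of a non-AF state
``event_cost:<state>``    cost         one-off cost of a tunnel state
``utility:<state>``       utility      health-state utility weight
=======================  ===========  =====================================

Shared ids (``state_cost``, ``event_cost``, ``utility``) broadcast the
same value to every strategy's :class:`~afecon.econ_eval.StateValues`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from .econ_eval import StateValues, StrategyOutcome, FrontierEntry, icer_frontier
from .errors import InvalidParameterError, SchemaError
from .model_core import (
    AuxiliaryClinicalParams,
    CohortTrace,
    EventRateTable,
    ModelConfig,
    TransitionMatrix,
    _assemble_matrix,
    _cycle_death_prob,
)
from .states import EVENTS, EVENT_STATE, STATE_ORDER, HealthState

__all__ = ["ModelBundle", "BaseCaseResult", "evaluate_strategy", "run_base_case"]

_AF = HealthState.AF.value
_DEAD = HealthState.DEAD.value


@dataclass
class ModelBundle:
    """A complete, runnable decision problem."""

    rates: EventRateTable
    values: Mapping[str, StateValues]  # keyed by strategy
    aux: AuxiliaryClinicalParams
    config: ModelConfig

    @property
    def strategies(self) -> list[str]:
        return list(self.values)

    # -- parameter addressing ------------------------------------------------

    def parameter_items(self) -> Iterator[tuple[str, float, str]]:
        """Yield ``(param_id, base_value, category)`` for every tunable input."""
        for strategy in self.strategies:
            for e in EVENTS:
                yield f"rate:{strategy}:{e}", self.rates[(strategy, e)].mean, "probability"
        for e in EVENTS:
            yield f"untreated_rate:{e}", self.aux.untreated_rates[e], "probability"
            yield f"fatality:{e}", self.aux.case_fatality[e], "probability"
        yield "disc_rate", self.aux.discontinuation_rate_per_100py, "probability"
        first = self.values[self.strategies[0]]
        for strategy in self.strategies:
            yield f"treatment_cost:{strategy}", self.values[strategy].per_cycle_cost(_AF), "cost"
        for state in STATE_ORDER:
            if state in (_AF, _DEAD):
                continue
            if first.per_cycle_cost(state) > 0:
                yield f"state_cost:{state}", first.per_cycle_cost(state), "cost"
            if first.event_cost.get(state, 0.0) > 0:
                yield f"event_cost:{state}", first.event_cost[state], "cost"
        for state in STATE_ORDER:
            if state != _DEAD:
                yield f"utility:{state}", first.utility[state], "utility"

    def get(self, param_id: str) -> float:
        for pid, value, _ in self.parameter_items():
            if pid == param_id:
                return value
        raise KeyError(param_id)

    def set(self, param_id: str, value: float) -> "ModelBundle":
        """Return a copy of the bundle with one parameter replaced."""
        kind, _, rest = param_id.partition(":")
        rates, aux = self.rates, self.aux
        values = {s: v.copy() for s, v in self.values.items()}
        if kind == "rate":
            strategy, _, event = rest.partition(":")
            frame = rates.to_frame()
            sel = (frame.strategy == strategy) & (frame.event == event)
            if not sel.any():
                raise KeyError(param_id)
            frame.loc[sel, "mean"] = value
            lo = frame.loc[sel, "ci_low"].iloc[0]
            hi = frame.loc[sel, "ci_high"].iloc[0]
            frame.loc[sel, "ci_low"] = min(lo, value)
            frame.loc[sel, "ci_high"] = max(hi, value)
            rates = EventRateTable.from_frame(frame)
        elif kind == "untreated_rate":
            aux = replace(aux, untreated_rates={**aux.untreated_rates, rest: value})
        elif kind == "fatality":
            aux = replace(aux, case_fatality={**aux.case_fatality, rest: value})
        elif kind == "disc_rate":
            aux = replace(aux, discontinuation_rate_per_100py=value)
        elif kind == "treatment_cost":
            if rest not in values:
                raise KeyError(param_id)
            values[rest] = values[rest].with_scaled_cost(_AF, value)
        elif kind == "state_cost":
            for s in values:
                values[s] = values[s].with_scaled_cost(rest, value)
        elif kind == "event_cost":
            for s in values:
                values[s].event_cost[rest] = value
        elif kind == "utility":
            for s in values:
                values[s].utility[rest] = value
        else:
            raise KeyError(param_id)
        return ModelBundle(rates=rates, values=values, aux=aux, config=self.config)


# ---------------------------------------------------------------------------
# numeric engine (canonical evaluation path)
# ---------------------------------------------------------------------------

class StrategyEngine:
    """Mutable numeric form of one strategy's model, for fast re-evaluation.

    The probabilistic sensitivity analysis writes sampled values straight
    into the engine's arrays and calls :meth:`evaluate`; the base case and
    DSA use the same path through :func:`evaluate_strategy`.
    """

    def __init__(self, bundle: ModelBundle, strategy: str):
        cfg = bundle.config
        self.config = cfg
        self.strategy = strategy
        self.event_rates = np.array(
            [bundle.rates[(strategy, e)].mean for e in EVENTS], dtype=float
        )
        self.untreated_rates = bundle.aux.untreated_vector()
        self.fatality = bundle.aux.fatality_vector()
        self.destinations = bundle.aux.destination_matrix()
        self.disc_rate = float(bundle.aux.discontinuation_rate_per_100py)
        self.post_mult = float(bundle.aux.post_event_mortality_multiplier)

        sv = bundle.values[strategy]
        states = list(STATE_ORDER)
        self.states = states
        self.recurring_cost = np.array([sv.per_cycle_cost(s) for s in states])
        self.event_cost = np.array([sv.event_cost.get(s, 0.0) for s in states])
        self.utility = np.array([sv.utility[s] for s in states])

        # per-cycle ages -> unique integer ages -> annual background mortality
        n = cfg.n_cycles
        ages = cfg.start_age + np.arange(n) * cfg.cycle_length
        ages_int = np.floor(ages + 1e-9).astype(int)
        self._uniq_ages, self._age_idx = np.unique(ages_int, return_inverse=True)
        self._annual_q = np.array(
            [bundle.aux.life_table.annual_prob(a) for a in self._uniq_ages]
        )
        times = np.arange(n) * cfg.cycle_length
        self._dfc = (1.0 + cfg.discount_cost) ** (-times)
        self._dfe = (1.0 + cfg.discount_effect) ** (-times)
        self._init = np.zeros(len(states))
        self._init[0] = cfg.cohort_size

    def _matrices(self) -> list[np.ndarray]:
        cl = self.config.cycle_length
        p_events = -np.expm1(-(self.event_rates / 100.0) * cl)
        p_untreated = -np.expm1(-(self.untreated_rates / 100.0) * cl)
        p_disc = -np.expm1(-(self.disc_rate / 100.0) * cl)
        out = []
        for q in self._annual_q:
            p_death = _cycle_death_prob(q, cl)
            p_death_post = _cycle_death_prob(min(1.0, q * self.post_mult), cl)
            out.append(
                _assemble_matrix(
                    p_events, p_untreated, p_disc, p_death, p_death_post,
                    self.fatality, self.destinations,
                )
            )
        return out

    def trace(self) -> CohortTrace:
        mats = self._matrices()
        n = self.config.n_cycles
        occ = np.empty((n + 1, len(self.states)))
        occ[0] = self._init
        idx = self._age_idx
        for t in range(n):
            occ[t + 1] = occ[t] @ mats[idx[t]]
        return CohortTrace(self.states, occ, self.config.cycle_length)

    def evaluate(self) -> StrategyOutcome:
        """Discounted per-patient cost and QALYs for the current arrays."""
        tr = self.trace()
        n = self.config.n_cycles
        occ = tr.occupancy[:n]
        if self.config.half_cycle_correction:
            occ_eff = 0.5 * (tr.occupancy[:n] + tr.occupancy[1 : n + 1])
        else:
            occ_eff = occ
        cost = float(
            self._dfc @ (occ_eff @ self.recurring_cost) + self._dfc @ (occ @ self.event_cost)
        )
        qaly = float(self._dfe @ (occ_eff @ self.utility) * self.config.cycle_length)
        size = self.config.cohort_size
        return StrategyOutcome(self.strategy, cost / size, qaly / size, cohort_size=size)

    def transition_matrices(self) -> list[TransitionMatrix]:
        """Validated per-unique-age matrices (diagnostic/inspection use)."""
        return [TransitionMatrix(self.states, m) for m in self._matrices()]


def evaluate_strategy(bundle: ModelBundle, strategy: str) -> StrategyOutcome:
    """Run one strategy through the canonical engine."""
    if strategy not in bundle.values:
        raise SchemaError(f"strategy {strategy!r} not in bundle ({bundle.strategies})")
    return StrategyEngine(bundle, strategy).evaluate()


@dataclass
class BaseCaseResult:
    outcomes: dict[str, StrategyOutcome]
    frontier: list[FrontierEntry]


def run_base_case(bundle: ModelBundle) -> BaseCaseResult:
    """Evaluate all strategies and build the cost-effectiveness frontier."""
    outcomes = {s: evaluate_strategy(bundle, s) for s in bundle.strategies}
    frontier = icer_frontier(list(outcomes.values()))
    return BaseCaseResult(outcomes=outcomes, frontier=frontier)
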