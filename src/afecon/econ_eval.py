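"""Economic evaluation: discounting, cost/QALY accumulation, frontier.

Costs follow a societal perspective and are split into direct medical
(DMC), direct non-medical (DNMC) and indirect (IC) components; indirect
costs use the human-capital approach (minimum wage x days of disability).
The cost-effectiveness frontier applies absolute and extended dominance
and chains incremental cost-effectiveness ratios (ICERs) along the
undominated strategies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError
from .model_core import CohortTrace, ModelConfig
from .states import HealthState

__all__ = [
    "StateValues",
    "StrategyOutcome",
    "FrontierEntry",
    "WageParams",
    "discount_factor",
    "accumulate",
    "indirect_cost",
    "monthly_wage_usd",
    "ppp_convert",
    "icer_frontier",
    "nmb",
]

log = logging.getLogger(__name__)

_COST_COMPONENTS = ("dmc", "dnmc", "ic")


@dataclass
class StateValues:
    """Per-state per-cycle costs (USD), one-off event costs and utilities.

    ``dmc``/``dnmc``/``ic`` are recurring per-cycle costs by state;
    ``event_cost`` is a one-off cost charged on (single-cycle) occupancy of
    a tunnel state; ``utility`` is the health-state utility weight.
    """

    dmc: dict[str, float]
    dnmc: dict[str, float]
    ic: dict[str, float]
    utility: dict[str, float]
    event_cost: dict[str, float]

    def __post_init__(self):
        dead = HealthState.DEAD.value
        for comp in (*_COST_COMPONENTS, "event_cost"):
            for state, v in getattr(self, comp).items():
                if v < 0:
                    raise InvalidParameterError(f"{comp}[{state}] must be non-negative, got {v}")
        for state, u in self.utility.items():
            if u > 1.0:
                raise InvalidParameterError(f"utility[{state}] must be <= 1, got {u}")
        if self.utility.get(dead, 0.0) != 0.0:
            raise InvalidParameterError("utility of DEAD must be 0")
        if any(getattr(self, c).get(dead, 0.0) != 0.0 for c in (*_COST_COMPONENTS, "event_cost")):
            raise InvalidParameterError("costs of DEAD must be 0")

    def states(self) -> list[str]:
        return list(self.utility)

    def per_cycle_cost(self, state: str) -> float:
        return self.dmc.get(state, 0.0) + self.dnmc.get(state, 0.0) + self.ic.get(state, 0.0)

    def total_cost(self, state: str) -> float:
        """Per-cycle cost including the one-off event cost of tunnel states."""
        return self.per_cycle_cost(state) + self.event_cost.get(state, 0.0)

    def cost_vector(self, states: Sequence[str]) -> np.ndarray:
        return np.array([self.total_cost(s) for s in states])

    def utility_vector(self, states: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.utility[s] for s in states])
        except KeyError as exc:
            raise SchemaError(f"state {exc.args[0]!r} missing from StateValues") from exc

    def with_scaled_cost(self, state: str, new_total_per_cycle: float) -> "StateValues":
        """Copy with the recurring cost of ``state`` rescaled to a new total.

        The DMC/DNMC/IC split is preserved proportionally (equal split when
        the current total is zero).
        """
        cur = self.per_cycle_cost(state)
        out = self.copy()
        if cur > 0:
            f = new_total_per_cycle / cur
            for comp in _COST_COMPONENTS:
                d = getattr(out, comp)
                if state in d:
                    d[state] *= f
        else:
            out.dmc[state] = new_total_per_cycle
        return out

    def copy(self) -> "StateValues":
        return StateValues(
            dmc=dict(self.dmc), dnmc=dict(self.dnmc), ic=dict(self.ic),
            utility=dict(self.utility), event_cost=dict(self.event_cost),
        )

    def to_frame(self) -> pd.DataFrame:
        states = self.states()
        return pd.DataFrame(
            {
                "state": states,
                "dmc": [self.dmc.get(s, 0.0) for s in states],
                "dnmc": [self.dnmc.get(s, 0.0) for s in states],
                "ic": [self.ic.get(s, 0.0) for s in states],
                "utility": [self.utility[s] for s in states],
                "event_cost": [self.event_cost.get(s, 0.0) for s in states],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StateValues":
        required = {"state", "dmc", "dnmc", "ic", "utility", "event_cost"}
        if not required.issubset(frame.columns):
            raise SchemaError(f"state-values table needs columns {sorted(required)}")
        get = lambda col: {str(r.state): float(getattr(r, col)) for r in frame.itertuples()}
        return cls(dmc=get("dmc"), dnmc=get("dnmc"), ic=get("ic"),
                   utility=get("utility"), event_cost=get("event_cost"))


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted per-patient totals for one strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    cohort_size: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.total_cost) and math.isfinite(self.total_qaly)):
            raise InvalidParameterError("outcome totals must be finite")
        if self.total_qaly < 0:
            raise InvalidParameterError("total QALYs must be non-negative")

    @property
    def cohort_cost(self) -> float:
        return self.total_cost * self.cohort_size

    @property
    def cohort_qaly(self) -> float:
        return self.total_qaly * self.cohort_size


@dataclass
class FrontierEntry:
    """One row of the cost-effectiveness frontier table."""

    strategy: str
    total_cost: float
    total_qaly: float
    acer: float
    dominance: str  # undominated | absolutely_dominated | extendedly_dominated
    icer: float | None = None
    incr_cost: float | None = None
    incr_qaly: float | None = None


@dataclass(frozen=True)
class WageParams:
    """Wage and exchange-rate inputs for human-capital indirect costing."""

    daily_wage_local: float = 1_769_428.0  # IRR
    exchange_rate: float = 409_841.0       # IRR per USD
    monthly_wage_local: float = 53_082_840.0  # IRR

    def __post_init__(self):
        if min(self.daily_wage_local, self.exchange_rate, self.monthly_wage_local) <= 0:
            raise InvalidParameterError("wage parameters must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def discount_factor(annual_rate: float, t: float) -> float:
    """Discrete-time discount factor ``1 / (1 + rate)^t`` at time ``t`` years."""
    if annual_rate < 0:
        raise InvalidParameterError(f"discount rate must be non-negative, got {annual_rate}")
    if t < 0:
        raise InvalidParameterError(f"time must be non-negative, got {t}")
    return (1.0 + annual_rate) ** (-t)


def accumulate(
    trace: CohortTrace,
    values: StateValues,
    config: ModelConfig,
) -> StrategyOutcome:
    """Attach costs and utilities to a trace and discount.

    Costs and QALYs are summed over cycles ``t = 0 .. n-1`` (state at cycle
    start), discounted at ``t * cycle_length`` years; QALYs weight utility
    by the cycle length. With the half-cycle correction enabled, recurring
    costs and utilities use the average of start- and end-of-cycle
    occupancy; one-off event costs always use start-of-cycle occupancy
    (each tunnel-state person-cycle is exactly one event). Totals are per
    patient (divide by cohort size).
    """
    missing = [s for s in trace.states if s not in values.utility]
    if missing:
        raise SchemaError(f"states {missing} missing from StateValues")
    n = trace.n_cycles
    cl = trace.cycle_length
    occ = trace.occupancy[:n]
    times = np.arange(n) * cl
    dfc = (1.0 + config.discount_cost) ** (-times)
    dfe = (1.0 + config.discount_effect) ** (-times)

    recurring = np.array([values.per_cycle_cost(s) for s in trace.states])
    one_off = np.array([values.event_cost.get(s, 0.0) for s in trace.states])
    util = values.utility_vector(trace.states)

    if config.half_cycle_correction:
        occ_eff = 0.5 * (trace.occupancy[:n] + trace.occupancy[1 : n + 1])
    else:
        occ_eff = occ

    cost = float(dfc @ (occ_eff @ recurring) + dfc @ (occ @ one_off))
    qaly = float(dfe @ (occ_eff @ util) * cl)
    size = trace.cohort_size
    return StrategyOutcome("", cost / size, qaly / size, cohort_size=size)


def indirect_cost(wages: WageParams, disability_days: float) -> float:
    """Human-capital indirect cost in USD: daily wage x days of disability."""
    if disability_days < 0:
        raise InvalidParameterError(f"disability days must be non-negative, got {disability_days}")
    return (wages.daily_wage_local / wages.exchange_rate) * disability_days


def monthly_wage_usd(wages: WageParams) -> float:
    """Minimum monthly wage converted to USD at the fixed exchange rate."""
    return wages.monthly_wage_local / wages.exchange_rate


def ppp_convert(amount_local: float, ppp_factor: float) -> float:
    """Convert a local-currency amount to USD with a PPP conversion factor."""
    if ppp_factor <= 0:
        raise InvalidParameterError("PPP factor must be positive")
    return amount_local / ppp_factor


def nmb(outcome: StrategyOutcome, threshold: float) -> float:
    """Net monetary benefit ``threshold * QALYs - cost`` at willingness-to-pay."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be non-negative")
    return threshold * outcome.total_qaly - outcome.total_cost


def _icer(a: StrategyOutcome, b: StrategyOutcome) -> float | None:
    """ICER of b relative to a; None when QALYs tie."""
    dq = b.total_qaly - a.total_qaly
    if dq == 0.0:
        return None
    return (b.total_cost - a.total_cost) / dq


def icer_frontier(outcomes: Sequence[StrategyOutcome]) -> list[FrontierEntry]:
    """Rank strategies, flag dominance, and chain ICERs.

    Strategies are sorted by ascending total cost. A strategy is absolutely
    dominated when another costs less with at least as many QALYs (or costs
    no more with strictly more QALYs). Extended dominance removes
    strategies that would produce a decreasing ICER sequence along the
    frontier. Each entry's ICER/incrementals are taken against the nearest
    cheaper frontier strategy; the cheapest frontier entry has none.
    """
    if len(outcomes) < 2:
        raise InvalidParameterError("frontier needs at least two strategies")
    ordered = sorted(outcomes, key=lambda o: (o.total_cost, o.total_qaly))

    def abs_dominated(s: StrategyOutcome) -> bool:
        for o in ordered:
            if o is s:
                continue
            if (o.total_cost < s.total_cost and o.total_qaly >= s.total_qaly) or (
                o.total_cost <= s.total_cost and o.total_qaly > s.total_qaly
            ):
                return True
        return False

    dominance = {
        o.strategy: ("absolutely_dominated" if abs_dominated(o) else "undominated")
        for o in ordered
    }

    # extended dominance: prune until ICERs strictly increase along the chain
    chain = [o for o in ordered if dominance[o.strategy] == "undominated"]
    changed = True
    while changed and len(chain) > 2:
        changed = False
        for i in range(1, len(chain) - 1):
            icer_in = _icer(chain[i - 1], chain[i])
            icer_out = _icer(chain[i], chain[i + 1])
            if icer_in is not None and icer_out is not None and icer_in >= icer_out:
                dominance[chain[i].strategy] = "extendedly_dominated"
                del chain[i]
                changed = True
                break

    frontier_set = {o.strategy for o in chain}
    entries: list[FrontierEntry] = []
    for o in ordered:
        acer = o.total_cost / o.total_qaly if o.total_qaly > 0 else math.inf
        entry = FrontierEntry(
            strategy=o.strategy,
            total_cost=o.total_cost,
            total_qaly=o.total_qaly,
            acer=acer,
            dominance=dominance[o.strategy],
        )
        # reference: most expensive frontier strategy cheaper than this one
        ref = None
        for cand in chain:
            if cand.strategy == o.strategy:
                break
            if cand.total_cost <= o.total_cost:
                ref = cand
        if ref is not None and ref.strategy != o.strategy:
            entry.incr_cost = o.total_cost - ref.total_cost
            entry.incr_qaly = o.total_qaly - ref.total_qaly
            entry.icer = _icer(ref, o)
            if entry.icer is None:
                log.warning(
                    "strategies %s and %s tie on QALYs; ICER undefined",
                    ref.strategy, o.strategy,
                )
        entries.append(entry)
    return entries


def frontier_frame(entries: Sequence[FrontierEntry]) -> pd.DataFrame:
    """Frontier as a DataFrame with report-style columns."""
    return pd.DataFrame(
        {
            "strategy": [e.strategy for e in entries],
            "total_cost": [round(e.total_cost, 2) for e in entries],
            "total_qaly": [round(e.total_qaly, 4) for e in entries],
            "icer": [None if e.icer is None else round(e.icer, 2) for e in entries],
            "incr_cost": [None if e.incr_cost is None else round(e.incr_cost, 2) for e in entries],
            "incr_qaly": [None if e.incr_qaly is None else round(e.incr_qaly, 4) for e in entries],
            "dominance": [e.dominance for e in entries],
            "acer": [round(e.acer, 3) for e in entries],
        }
    )
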