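"""Cohort Markov engine: rates to probabilities, transition matrices, traces.

Event frequencies enter the model as rates per 100 patient-years (the form
reported by anticoagulation trials) and are converted to per-cycle
probabilities under a constant-hazard assumption. A transition matrix is
built per model cycle (age-dependent background mortality), and a cohort of
fixed size is propagated through the matrices to produce a state-occupancy
trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateParameterError, InvalidParameterError, SchemaError
from .states import EVENTS, EVENT_STATE, STATE_ORDER, STRATEGIES, HealthState

__all__ = [
    "EventRate",
    "EventRateTable",
    "ModelConfig",
    "LifeTable",
    "AuxiliaryClinicalParams",
    "TransitionMatrix",
    "CohortTrace",
    "rate_to_cycle_prob",
    "build_transition_matrix",
    "run_cohort",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventRate:
    """An event rate per 100 patient-years with its 95% confidence interval."""

    mean: float
    ci_low: float
    ci_high: float

    def validate(self, label: str = "") -> None:
        vals = (self.mean, self.ci_low, self.ci_high)
        if not all(math.isfinite(v) and v >= 0 for v in vals):
            raise InvalidParameterError(f"{label}: rates must be finite and non-negative, got {vals}")
        if self.ci_low > self.ci_high:
            raise InvalidParameterError(f"{label}: ci_low {self.ci_low} > ci_high {self.ci_high}")
        if not (self.ci_low <= self.mean <= self.ci_high):
            # Published tables occasionally print a mean outside its own CI;
            # keep the value but flag it.
            warnings.warn(
                f"{label}: mean {self.mean} outside CI ({self.ci_low}, {self.ci_high}); "
                "stored as given",
                stacklevel=2,
            )


class EventRateTable:
    """Per-strategy, per-event rates per 100 patient-years with 95% CIs."""

    def __init__(self, rates: Mapping[tuple[str, str], EventRate]):
        self._rates = dict(rates)
        for (strategy, event), er in self._rates.items():
            if event not in EVENTS:
                raise SchemaError(f"unknown event {event!r}")
            er.validate(f"{strategy}/{event}")

    def __getitem__(self, key: tuple[str, str]) -> EventRate:
        return self._rates[key]

    def strategies(self) -> list[str]:
        seen: dict[str, None] = {}
        for strategy, _ in self._rates:
            seen.setdefault(strategy)
        return list(seen)

    def rates_for(self, strategy: str) -> dict[str, float]:
        """Mean rate per event for one strategy, in canonical event order."""
        return {e: self._rates[(strategy, e)].mean for e in EVENTS}

    def items(self):
        return self._rates.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strategy": s, "event": e, "mean": er.mean, "ci_low": er.ci_low, "ci_high": er.ci_high}
            for (s, e), er in self._rates.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventRateTable":
        required = {"strategy", "event", "mean", "ci_low", "ci_high"}
        if not required.issubset(frame.columns):
            raise SchemaError(f"event-rate table needs columns {sorted(required)}")
        rates = {
            (str(r.strategy), str(r.event)): EventRate(float(r.mean), float(r.ci_low), float(r.ci_high))
            for r in frame.itertuples()
        }
        return cls(rates)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventRateTable) and self._rates == other._rates


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings.

    cycle_length
        Cycle length in years; default one month. A six-week cycle
        (``6/52.18``) is an equally defensible alternative and is supported.
    horizon
        Simulated time horizon in years (default 30).
    cohort_size
        Persons in the simulated cohort (default 1000).
    start_age
        Cohort entry age in years (default 50).
    discount_cost / discount_effect
        Annual discount rates: 7.2% for costs, 3% for health outcomes.
    threshold
        Willingness-to-pay threshold in USD per QALY (default 11 134,
        Iran's 2023 per-capita GDP converted at purchasing power parity).
    """

    cycle_length: float = 1.0 / 12.0
    horizon: float = 30.0
    cohort_size: float = 1000.0
    start_age: float = 50.0
    discount_cost: float = 0.072
    discount_effect: float = 0.03
    threshold: float = 11134.0
    half_cycle_correction: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise InvalidParameterError("cycle_length must be positive")
        if self.horizon < self.cycle_length:
            raise InvalidParameterError("horizon must cover at least one cycle")
        for name in ("discount_cost", "discount_effect"):
            r = getattr(self, name)
            if not (0 <= r < 1):
                raise InvalidParameterError(f"{name} must lie in [0, 1)")
        if self.cohort_size < 1:
            raise InvalidParameterError("cohort_size must be >= 1")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


class LifeTable:
    """Age-indexed annual death probabilities with constant extrapolation."""

    def __init__(self, ages: Sequence[float], annual_death_prob: Sequence[float]):
        ages = np.asarray(ages, dtype=float)
        qx = np.asarray(annual_death_prob, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise SchemaError("life table needs matching 1-D age and probability columns")
        if np.any(np.diff(ages) <= 0):
            raise SchemaError("life-table ages must be strictly increasing")
        if np.any((qx < 0) | (qx > 1)):
            raise InvalidParameterError("annual death probabilities must lie in [0, 1]")
        self.ages = ages
        self.qx = qx

    def annual_prob(self, age: float) -> float:
        """Annual death probability at ``floor(age)``, clamped to the table range."""
        a = math.floor(age)
        if a <= self.ages[0]:
            return float(self.qx[0])
        if a >= self.ages[-1]:
            return float(self.qx[-1])
        idx = int(np.searchsorted(self.ages, a, side="right") - 1)
        return float(self.qx[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_death_prob": self.qx})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        if not {"age", "annual_death_prob"}.issubset(frame.columns):
            raise SchemaError("life table needs columns ['age', 'annual_death_prob']")
        return cls(frame["age"].to_numpy(), frame["annual_death_prob"].to_numpy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.qx, other.qx)
        )


_DEST_KEYS = ("to_af", "to_af_no_ac", "to_post_event")


@dataclass(frozen=True)
class AuxiliaryClinicalParams:
    """Clinical parameters beyond the per-strategy event rates.

    case_fatality
        Fraction of each acute event that is fatal within its cycle.
    destinations
        For event survivors, the split over (back to anticoagulated AF,
        AF without anticoagulation, chronic post-event state); sums to 1.
    discontinuation_rate_per_100py
        Event-unrelated anticoagulant discontinuation, per 100 patient-years.
    untreated_rates
        Event rates per 100 PY applying in the AF-without-anticoagulation
        state (off-treatment risk profile).
    life_table
        Background (all-cause, event-unrelated) mortality by age.
    post_event_mortality_multiplier
        Hazard multiplier on background mortality in the post-event state.
    """

    case_fatality: Mapping[str, float]
    destinations: Mapping[str, tuple[float, float, float]]
    discontinuation_rate_per_100py: float
    untreated_rates: Mapping[str, float]
    life_table: LifeTable
    post_event_mortality_multiplier: float = 1.0

    def __post_init__(self):
        for e in EVENTS:
            f = self.case_fatality[e]
            if not (0.0 <= f <= 1.0):
                raise InvalidParameterError(f"case fatality for {e} must lie in [0,1], got {f}")
            d = self.destinations[e]
            if len(d) != 3 or any(x < 0 for x in d):
                raise InvalidParameterError(f"destination split for {e} must be 3 non-negative shares")
            if abs(sum(d) - 1.0) > 1e-12:
                raise InvalidParameterError(
                    f"destination split for {e} sums to {sum(d)!r}, expected 1"
                )
            if self.untreated_rates[e] < 0:
                raise InvalidParameterError(f"untreated rate for {e} must be non-negative")
        if self.discontinuation_rate_per_100py < 0:
            raise InvalidParameterError("discontinuation rate must be non-negative")
        if self.post_event_mortality_multiplier < 0:
            raise InvalidParameterError("mortality multiplier must be non-negative")

    def fatality_vector(self) -> np.ndarray:
        return np.array([self.case_fatality[e] for e in EVENTS], dtype=float)

    def destination_matrix(self) -> np.ndarray:
        return np.array([self.destinations[e] for e in EVENTS], dtype=float)

    def untreated_vector(self) -> np.ndarray:
        return np.array([self.untreated_rates[e] for e in EVENTS], dtype=float)


# ---------------------------------------------------------------------------
# matrices and traces
# ---------------------------------------------------------------------------

class TransitionMatrix:
    """Row-stochastic per-cycle transition matrix over named states."""

    def __init__(self, states: Sequence[str], array: np.ndarray):
        array = np.asarray(array, dtype=float)
        n = len(states)
        if array.shape != (n, n):
            raise SchemaError(f"matrix shape {array.shape} does not match {n} states")
        self.states = list(states)
        self.array = array
        self.validate()

    def validate(self, atol: float = 1e-10) -> None:
        if np.any((self.array < -atol) | (self.array > 1 + atol)):
            raise InvalidParameterError("transition probabilities must lie in [0, 1]")
        rowsums = self.array.sum(axis=1)
        bad = np.where(np.abs(rowsums - 1.0) > atol)[0]
        if bad.size:
            i = int(bad[0])
            raise InvalidParameterError(
                f"row {self.states[i]!r} sums to {rowsums[i]!r}, expected 1"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.array, index=self.states, columns=self.states)


class CohortTrace:
    """State occupancy of a closed cohort over cycles.

    Row ``t`` is the person-count per state at the *start* of cycle ``t``;
    row 0 is the initial distribution, and there are ``n_cycles + 1`` rows.
    """

    def __init__(self, states: Sequence[str], occupancy: np.ndarray, cycle_length: float):
        occupancy = np.asarray(occupancy, dtype=float)
        if occupancy.ndim != 2 or occupancy.shape[1] != len(states):
            raise SchemaError("occupancy must be (cycles+1) x n_states")
        self.states = list(states)
        self.occupancy = occupancy
        self.cycle_length = float(cycle_length)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    @property
    def cycle_times(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0]) * self.cycle_length

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancy, columns=self.states)
        frame.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        frame.insert(1, "time_years", self.cycle_times)
        return frame

    def check_conservation(self, atol: float = 1e-8) -> None:
        totals = self.occupancy.sum(axis=1)
        if np.any(np.abs(totals - self.cohort_size) > atol):
            raise InvalidParameterError("cohort size not conserved across cycles")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rate_to_cycle_prob(rate_per_100py: float, cycle_length: float) -> float:
    """Convert a rate per 100 patient-years to a per-cycle probability.

    Uses the constant-hazard (exponential) relation
    ``p = 1 - exp(-(rate/100) * cycle_length)``.
    """
    if rate_per_100py < 0:
        raise InvalidParameterError(f"rate must be non-negative, got {rate_per_100py}")
    if cycle_length <= 0:
        raise InvalidParameterError(f"cycle length must be positive, got {cycle_length}")
    return -math.expm1(-(rate_per_100py / 100.0) * cycle_length)


def _cycle_death_prob(annual_q: float, cycle_length: float) -> float:
    """Per-cycle death probability from an annual probability."""
    annual_q = min(max(annual_q, 0.0), 1.0)
    if annual_q >= 1.0:
        return 1.0
    return 1.0 - (1.0 - annual_q) ** cycle_length


def _assemble_matrix(
    p_events: np.ndarray,
    p_untreated: np.ndarray,
    p_disc: float,
    p_death: float,
    p_death_post: float,
    fatality: np.ndarray,
    destinations: np.ndarray,
) -> np.ndarray:
    """Assemble the 11x11 transition array from per-cycle probabilities.

    Single canonical construction shared by the public builder and the
    vectorised evaluation engine, so that both produce bit-identical rows.
    """
    n = len(STATE_ORDER)
    i_af, i_no_ac, i_post, i_dead = 0, 8, 9, 10
    m = np.zeros((n, n))

    exits = float(p_events.sum() + p_disc + p_death)
    if exits > 1.0:
        raise DegenerateParameterError(HealthState.AF.value, exits)
    m[i_af, 1:8] = p_events
    m[i_af, i_no_ac] = p_disc
    m[i_af, i_dead] = p_death
    m[i_af, i_af] = 1.0 - exits

    surv = 1.0 - fatality
    m[1:8, i_dead] = fatality
    m[1:8, i_af] = surv * destinations[:, 0]
    m[1:8, i_no_ac] = surv * destinations[:, 1]
    m[1:8, i_post] = surv * destinations[:, 2]

    exits_u = float(p_untreated.sum() + p_death)
    if exits_u > 1.0:
        raise DegenerateParameterError(HealthState.AF_NO_AC.value, exits_u)
    m[i_no_ac, 1:8] = p_untreated
    m[i_no_ac, i_dead] = p_death
    m[i_no_ac, i_no_ac] = 1.0 - exits_u

    m[i_post, i_dead] = p_death_post
    m[i_post, i_post] = 1.0 - p_death_post

    m[i_dead, i_dead] = 1.0
    return m


def build_transition_matrix(
    rates: Mapping[str, float],
    aux: AuxiliaryClinicalParams,
    age: float,
    config: ModelConfig,
) -> TransitionMatrix:
    """Build the per-cycle transition matrix for one strategy at one age.

    ``rates`` maps event name to a mean rate per 100 PY (see
    :meth:`EventRateTable.rates_for`). The anticoagulated-AF row combines
    converted event probabilities, event-unrelated discontinuation and
    age-specific background death, with the residual as a self-loop; event
    tunnel rows route the case-fatality fraction to death and survivors per
    the destination split.
    """
    cl = config.cycle_length
    p_events = np.array([rate_to_cycle_prob(rates[e], cl) for e in EVENTS])
    p_untreated = np.array([rate_to_cycle_prob(aux.untreated_rates[e], cl) for e in EVENTS])
    p_disc = rate_to_cycle_prob(aux.discontinuation_rate_per_100py, cl)
    q = aux.life_table.annual_prob(age)
    p_death = _cycle_death_prob(q, cl)
    p_death_post = _cycle_death_prob(
        min(1.0, q * aux.post_event_mortality_multiplier), cl
    )
    array = _assemble_matrix(
        p_events, p_untreated, p_disc, p_death, p_death_post,
        aux.fatality_vector(), aux.destination_matrix(),
    )
    return TransitionMatrix(STATE_ORDER, array)


def run_cohort(
    matrices: TransitionMatrix | Sequence[TransitionMatrix],
    init: Sequence[float],
    n_cycles: int,
    cycle_length: float = 1.0 / 12.0,
) -> CohortTrace:
    """Propagate a cohort: ``occupancy[t+1] = occupancy[t] @ matrix[t]``.

    A single matrix is reused for every cycle; a sequence must supply at
    least ``n_cycles`` matrices (age-varying model).
    """
    if isinstance(matrices, TransitionMatrix):
        seq: Sequence[TransitionMatrix] = [matrices] * n_cycles
    else:
        seq = list(matrices)
        if len(seq) < n_cycles:
            raise InvalidParameterError(
                f"need at least {n_cycles} matrices, got {len(seq)}"
            )
    states = seq[0].states if seq else list(STATE_ORDER)
    init = np.asarray(init, dtype=float)
    if init.shape != (len(states),):
        raise SchemaError(
            f"initial occupancy has shape {init.shape}, expected ({len(states)},)"
        )
    occ = np.empty((n_cycles + 1, len(states)))
    occ[0] = init
    for t in range(n_cycles):
        m = seq[t]
        if m.states != states:
            raise SchemaError("all matrices must share the same state set and order")
        occ[t + 1] = occ[t] @ m.array
    return CohortTrace(states, occ, cycle_length)
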