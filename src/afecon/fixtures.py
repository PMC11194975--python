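"""Packaged inputs and synthetic parameter sets.

The package ships two kinds of inputs, each tagged with a provenance:

``published``
    Values printed in the source tables: the per-strategy event rates with
    95% CIs, and the budget-impact population, market-share and budget
    tables. These are stored verbatim as CSVs and checksum-verified on
    load.
``synthetic``
    Per-state costs and utilities, case-fatality fractions, event
    destinations, the off-treatment risk profile and the background life
    table. The study that motivated this model kept these in supplementary
    material, so the package supplies a coherent synthetic set chosen from
    NVAF modelling literature orders of magnitude. They are defaults, not
    estimates of the withheld values.
``calibrated``
    The per-patient annual treatment costs of the budget-impact model,
    least-squares fitted to the fifteen published scenario-year budgets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .analysis import ModelBundle
from .bia import (
    TREATMENTS,
    MarketShareScenario,
    PopulationProjection,
    TreatmentCostSet,
)
from .econ_eval import StateValues
from .errors import CorruptedFixtureError, InvalidParameterError
from .model_core import (
    AuxiliaryClinicalParams,
    EventRateTable,
    LifeTable,
    ModelConfig,
    TransitionMatrix,
)
from .states import EVENTS, STATE_ORDER, STRATEGIES, HealthState

__all__ = [
    "FixtureBundle",
    "BIAInputs",
    "SynthSpec",
    "load_reference_fixture",
    "default_bundle",
    "synthetic_life_table",
    "default_aux_params",
    "default_state_values",
    "generate_parameter_set",
    "calibrate_treatment_costs",
    "make_toy_model",
]

_CHECKSUMS = {
    "event_rates.csv": "7cc6ef7a4877f0ccb50cac3d72b4dc07c87fc4a40dafae427a4a9c953004a211",
    "bia_population.csv": "b7784b0d3b44246d9914bbce420196a7ed7956fd6053e66e1f46fefac7053e2f",
    "bia_market_shares.csv": "41f05af3fae76355e0fc12fe8aa677daf62947a57dcd8212f3fdafc20d8b969d",
    "bia_budgets.csv": "0d48b22e6df9cc39e82dbd1a09285d578377bddb625476b35df8502d30778921",
}


def _read_packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("afecon").joinpath("data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise CorruptedFixtureError(
            f"packaged file {name} has checksum {digest}, expected {_CHECKSUMS[name]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


# ---------------------------------------------------------------------------
# synthetic clinical and economic defaults
# ---------------------------------------------------------------------------

def synthetic_life_table() -> LifeTable:
    """Synthetic Gompertz-style background mortality, ages 30-110.

    Annual death probability ``q(a) = min(0.6, 6e-4 * exp(0.085 (a - 30)))``,
    giving roughly 0.3% at 50, 1.8% at 70 and 10% at 90 — the shape of a
    middle-income-country adult life table, not any official table.
    """
    ages = np.arange(30, 111)
    qx = np.minimum(0.6, 6e-4 * np.exp(0.085 * (ages - 30)))
    return LifeTable(ages, qx)


#: Synthetic case-fatality fraction per acute event (death within the
#: one-cycle tunnel state; longer-term harm flows through the post-event
#: state). SE covers severe systemic arterial embolism, hence the high
#: acute fatality.
_FATALITY = {
    "ischemic_stroke": 0.08,
    "se": 0.28,
    "ich": 0.22,
    "other_mb": 0.02,
    "crnmb": 0.0,
    "mi": 0.08,
    "cv_hosp": 0.055,
}

#: Synthetic survivor destinations (to AF, to AF off anticoagulation, to post-event).
_DESTINATIONS = {
    "ischemic_stroke": (0.65, 0.05, 0.30),
    "se": (0.70, 0.00, 0.30),
    "ich": (0.30, 0.40, 0.30),
    "other_mb": (0.70, 0.30, 0.00),
    "crnmb": (0.95, 0.05, 0.00),
    "mi": (0.70, 0.00, 0.30),
    "cv_hosp": (1.00, 0.00, 0.00),
}

#: Synthetic off-treatment event rates per 100 PY (AF without anticoagulation).
_UNTREATED_RATES = {
    "ischemic_stroke": 2.5,
    "se": 0.30,
    "ich": 0.30,
    "other_mb": 0.80,
    "crnmb": 1.00,
    "mi": 0.80,
    "cv_hosp": 10.46,
}

#: Synthetic monthly management cost of anticoagulated AF, by strategy,
#: split (DMC, DNMC, IC) in USD. Warfarin's split reflects the societal
#: burden of monthly INR monitoring (visits, transport, lost wages), which
#: in Iran exceeds the generic-DOAC acquisition premium.
_AF_COST = {
    "apixaban": (10.0, 0.5, 0.5),
    "rivaroxaban": (9.0, 0.5, 0.5),
    "vka": (8.0, 4.0, 7.0),
}

#: Synthetic recurring monthly costs (DMC, DNMC, IC) of non-AF states.
_STATE_COST = {
    HealthState.AF_NO_AC.value: (1.0, 0.3, 0.3),
    HealthState.POST_EVENT.value: (25.0, 5.0, 10.0),
}

#: Synthetic one-off acute event costs (USD) charged in the tunnel cycle.
_EVENT_COST = {
    HealthState.ISCHEMIC_STROKE.value: 1200.0,
    HealthState.SE.value: 700.0,
    HealthState.ICH.value: 1500.0,
    HealthState.OTHER_MB.value: 500.0,
    HealthState.CRNMB.value: 80.0,
    HealthState.MI.value: 1000.0,
    HealthState.CV_HOSP.value: 400.0,
}

#: Synthetic health-state utilities (EQ-5D-like weights).
_UTILITY = {
    HealthState.AF.value: 0.80,
    HealthState.ISCHEMIC_STROKE.value: 0.55,
    HealthState.SE.value: 0.65,
    HealthState.ICH.value: 0.45,
    HealthState.OTHER_MB.value: 0.65,
    HealthState.CRNMB.value: 0.75,
    HealthState.MI.value: 0.60,
    HealthState.CV_HOSP.value: 0.70,
    HealthState.AF_NO_AC.value: 0.78,
    HealthState.POST_EVENT.value: 0.75,
    HealthState.DEAD.value: 0.0,
}

_POST_EVENT_MORTALITY_MULTIPLIER = 1.2
_DISCONTINUATION_RATE = 5.0  # per 100 PY


def default_aux_params() -> AuxiliaryClinicalParams:
    """Synthetic auxiliary clinical parameters (see module docstring)."""
    return AuxiliaryClinicalParams(
        case_fatality=dict(_FATALITY),
        destinations={e: tuple(d) for e, d in _DESTINATIONS.items()},
        discontinuation_rate_per_100py=_DISCONTINUATION_RATE,
        untreated_rates=dict(_UNTREATED_RATES),
        life_table=synthetic_life_table(),
        post_event_mortality_multiplier=_POST_EVENT_MORTALITY_MULTIPLIER,
    )


def default_state_values(strategy: str) -> StateValues:
    """Synthetic per-state costs and utilities for one strategy.

    Only the anticoagulated-AF management cost differs between strategies;
    event, off-treatment and post-event values are shared.
    """
    if strategy not in _AF_COST:
        raise InvalidParameterError(f"unknown strategy {strategy!r}")
    dmc = {s: 0.0 for s in STATE_ORDER}
    dnmc = {s: 0.0 for s in STATE_ORDER}
    ic = {s: 0.0 for s in STATE_ORDER}
    dmc[HealthState.AF.value], dnmc[HealthState.AF.value], ic[HealthState.AF.value] = _AF_COST[strategy]
    for state, (a, b, c) in _STATE_COST.items():
        dmc[state], dnmc[state], ic[state] = a, b, c
    event_cost = {s: _EVENT_COST.get(s, 0.0) for s in STATE_ORDER}
    return StateValues(dmc=dmc, dnmc=dnmc, ic=ic, utility=dict(_UTILITY), event_cost=event_cost)


def load_event_rates() -> EventRateTable:
    """Published per-strategy event rates per 100 PY with 95% CIs."""
    import warnings

    with warnings.catch_warnings():
        # the published VKA ICH mean sits below its printed CI; stored verbatim
        warnings.simplefilter("ignore")
        return EventRateTable.from_frame(_read_packaged_csv("event_rates.csv"))


def default_bundle(config: ModelConfig | None = None) -> ModelBundle:
    """The packaged decision problem: published rates + synthetic values."""
    return ModelBundle(
        rates=load_event_rates(),
        values={s: default_state_values(s) for s in STRATEGIES},
        aux=default_aux_params(),
        config=config or ModelConfig(),
    )


# ---------------------------------------------------------------------------
# budget-impact inputs
# ---------------------------------------------------------------------------

@dataclass
class BIAInputs:
    """Budget-impact inputs: projection, scenario shares, published budgets."""

    projection: PopulationProjection
    scenarios: dict[str, MarketShareScenario]
    published_budgets: dict[str, dict[int, float]]
    treatment_costs: TreatmentCostSet  # calibrated


def _redistribute(shares: dict[str, float], removed: str) -> dict[str, float]:
    """Remove one treatment and spread its share over the rest, pro rata."""
    rest = {t: s for t, s in shares.items() if t != removed}
    total = sum(rest.values())
    return {t: s / total for t, s in rest.items()} | {removed: 0.0}


def load_bia_inputs() -> BIAInputs:
    """Published BIA tables plus synthetic scenario shares and calibrated costs.

    Scenario 2 ("all medicines") uses the published market shares. The
    published tables do not state how shares are reallocated when a drug is
    absent; scenarios 1 (no apixaban) and 3 (no rivaroxaban) here
    redistribute the removed drug's share proportionally (tagged
    synthetic). Treatment costs are least-squares calibrated to the
    fifteen published scenario-year budgets.
    """
    pop = _read_packaged_csv("bia_population.csv")
    shares = _read_packaged_csv("bia_market_shares.csv")
    budgets = _read_packaged_csv("bia_budgets.csv")

    projection = PopulationProjection(
        national={int(r.year): int(r.national_population) for r in pop.itertuples()},
        eligible={int(r.year): int(r.eligible_patients) for r in pop.itertuples()},
    )
    base_shares = {
        int(r.year): {t: float(getattr(r, t)) for t in TREATMENTS}
        for r in shares.itertuples()
    }
    scenarios = {
        "scenario1": MarketShareScenario(
            "scenario1", {y: _redistribute(s, "apixaban") for y, s in base_shares.items()}
        ),
        "scenario2": MarketShareScenario("scenario2", base_shares),
        "scenario3": MarketShareScenario(
            "scenario3", {y: _redistribute(s, "rivaroxaban") for y, s in base_shares.items()}
        ),
    }
    published = {
        f"scenario{k}": {int(r.year): float(getattr(r, f"scenario{k}")) for r in budgets.itertuples()}
        for k in (1, 2, 3)
    }
    published["impact_1_2"] = {int(r.year): float(r.impact_1_2) for r in budgets.itertuples()}
    published["impact_1_3"] = {int(r.year): float(r.impact_1_3) for r in budgets.itertuples()}
    costs = calibrate_treatment_costs(projection, scenarios, published)
    return BIAInputs(projection, scenarios, published, costs)


def calibrate_treatment_costs(
    projection: PopulationProjection,
    scenarios: Mapping[str, MarketShareScenario],
    published_budgets: Mapping[str, Mapping[int, float]],
) -> TreatmentCostSet:
    """Non-negative least-squares fit of per-patient annual treatment costs.

    Each published scenario-year budget gives one linear equation
    ``patients x sum_t share_t x cost_t = budget``; the four treatment
    costs are fitted jointly across all scenario-year combinations.
    """
    rows, rhs = [], []
    for sid, scenario in scenarios.items():
        if sid not in published_budgets:
            continue
        for y in projection.years:
            n = projection.eligible[y]
            rows.append([n * scenario.shares[y].get(t, 0.0) for t in TREATMENTS])
            rhs.append(published_budgets[sid][y])
    coef, _ = nnls(np.asarray(rows, dtype=float), np.asarray(rhs, dtype=float))
    return TreatmentCostSet(dict(zip(TREATMENTS, coef)))


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """A complete runnable input set with per-group provenance tags."""

    model: ModelBundle
    bia: BIAInputs
    provenance: dict[str, str] = field(default_factory=dict)


def load_reference_fixture() -> FixtureBundle:
    """The packaged fixture: published tables plus synthetic defaults."""
    return FixtureBundle(
        model=default_bundle(),
        bia=load_bia_inputs(),
        provenance={
            "event_rates": "published",
            "bia_population": "published",
            "bia_market_shares": "published",
            "bia_budgets": "published",
            "bia_scenario_1_3_shares": "synthetic",
            "bia_treatment_costs": "calibrated",
            "state_values": "synthetic",
            "aux_clinical": "synthetic",
            "life_table": "synthetic",
            "model_config": "published",
        },
    )


# ---------------------------------------------------------------------------
# synthetic parameter-set generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthSpec:
    """Settings for drawing a random but coherent parameter set.

    ``cost_scale_range`` multiplies every synthetic default cost by a
    uniform draw; ``utility_jitter`` perturbs utilities (the ordering
    ``utility(event/post states) <= utility(AF) <= 1`` is enforced);
    ``fatality_scale_range`` rescales case-fatality fractions (clipped to
    [0, 1]).
    """

    seed: int = 0
    cost_scale_range: tuple[float, float] = (0.7, 1.3)
    utility_jitter: float = 0.05
    fatality_scale_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self):
        lo, hi = self.cost_scale_range
        flo, fhi = self.fatality_scale_range
        if not (0 < lo <= hi and 0 < flo <= fhi and 0 <= self.utility_jitter < 0.5):
            raise InvalidParameterError("infeasible synthesis ranges")


def generate_parameter_set(spec: SynthSpec) -> FixtureBundle:
    """Draw a complete, model-runnable parameter set around the defaults.

    Deterministic for a given seed. Published tables are kept verbatim;
    every drawn quantity is tagged synthetic.
    """
    rng = np.random.default_rng(spec.seed)
    fixture = load_reference_fixture()
    bundle = fixture.model

    af = HealthState.AF.value
    u_af = float(np.clip(_UTILITY[af] + rng.uniform(-spec.utility_jitter, spec.utility_jitter), 0.05, 1.0))
    values: dict[str, StateValues] = {}
    utility = {}
    for state in STATE_ORDER:
        if state == HealthState.DEAD.value:
            utility[state] = 0.0
        elif state == af:
            utility[state] = u_af
        else:
            u = _UTILITY[state] + rng.uniform(-spec.utility_jitter, spec.utility_jitter)
            # severity ordering: no state outranks anticoagulated AF
            utility[state] = float(np.clip(u, 0.0, u_af))
    cost_scale = rng.uniform(*spec.cost_scale_range)
    for strategy in STRATEGIES:
        sv = default_state_values(strategy)
        for comp in (sv.dmc, sv.dnmc, sv.ic, sv.event_cost):
            for state in comp:
                comp[state] *= cost_scale
        sv.utility = dict(utility)
        values[strategy] = sv

    fat_scale = rng.uniform(*spec.fatality_scale_range)
    fatality = {e: float(np.clip(_FATALITY[e] * fat_scale, 0.0, 1.0)) for e in EVENTS}
    aux = AuxiliaryClinicalParams(
        case_fatality=fatality,
        destinations={e: tuple(d) for e, d in _DESTINATIONS.items()},
        discontinuation_rate_per_100py=_DISCONTINUATION_RATE,
        untreated_rates=dict(_UNTREATED_RATES),
        life_table=synthetic_life_table(),
        post_event_mortality_multiplier=_POST_EVENT_MORTALITY_MULTIPLIER,
    )
    model = ModelBundle(rates=bundle.rates, values=values, aux=aux, config=bundle.config)
    provenance = dict(fixture.provenance)
    provenance.update({"state_values": "synthetic", "aux_clinical": "synthetic"})
    return FixtureBundle(model=model, bia=fixture.bia, provenance=provenance)


# ---------------------------------------------------------------------------
# toy models with closed-form answers (oracle factory)
# ---------------------------------------------------------------------------

def make_toy_model(
    n_states: int = 2,
    death_prob: float = 0.1,
    cost: float = 0.0,
    utility: float = 1.0,
    n_cycles: int = 10,
    cycle_length: float = 1.0,
    discount_cost: float = 0.0,
    discount_effect: float = 0.0,
    cohort_size: float = 1000.0,
) -> dict:
    """A 2- or 3-state survival chain plus its analytic cost/QALY totals.

    2 states: ALIVE -> DEAD with per-cycle probability ``death_prob``.
    3 states: WELL -> SICK -> DEAD, both steps with ``death_prob``.
    The analytic per-patient totals use geometric-series closed forms (for
    the 2-state chain), independent of the cohort engine.
    """
    if n_states not in (2, 3):
        raise InvalidParameterError("toy model supports 2 or 3 states")
    p = death_prob
    if n_states == 2:
        states = ["ALIVE", "DEAD"]
        m = np.array([[1 - p, p], [0.0, 1.0]])
        # per-patient sums over t = 0..n-1 of (1-p)^t / (1+r)^(t*cl)
        def geo(rate: float) -> float:
            ratio = (1 - p) / (1 + rate) ** cycle_length
            if ratio == 1.0:
                return float(n_cycles)
            return (1 - ratio**n_cycles) / (1 - ratio)

        analytic = {
            "qaly_per_patient": utility * cycle_length * geo(discount_effect),
            "cost_per_patient": cost * geo(discount_cost),
        }
        values = StateValues(
            dmc={"ALIVE": cost, "DEAD": 0.0},
            dnmc={"ALIVE": 0.0, "DEAD": 0.0},
            ic={"ALIVE": 0.0, "DEAD": 0.0},
            utility={"ALIVE": utility, "DEAD": 0.0},
            event_cost={"ALIVE": 0.0, "DEAD": 0.0},
        )
        init = np.array([cohort_size, 0.0])
    else:
        states = ["WELL", "SICK", "DEAD"]
        m = np.array([[1 - p, p, 0.0], [0.0, 1 - p, p], [0.0, 0.0, 1.0]])
        analytic = {}
        values = StateValues(
            dmc={"WELL": cost, "SICK": cost, "DEAD": 0.0},
            dnmc={s: 0.0 for s in states},
            ic={s: 0.0 for s in states},
            utility={"WELL": utility, "SICK": utility, "DEAD": 0.0},
            event_cost={s: 0.0 for s in states},
        )
        init = np.array([cohort_size, 0.0, 0.0])
    config = ModelConfig(
        cycle_length=cycle_length,
        horizon=n_cycles * cycle_length,
        cohort_size=cohort_size,
        discount_cost=discount_cost,
        discount_effect=discount_effect,
    )
    return {
        "states": states,
        "matrix": TransitionMatrix(states, m),
        "init": init,
        "values": values,
        "config": config,
        "analytic": analytic,
    }
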