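"""Five-year budget-impact analysis over market-share scenarios.

The eligible NVAF population is projected from national population counts
and a prevalence fraction (patients aged 50+). Each scenario assigns
yearly market shares to the available anticoagulants; the yearly budget is
``patients x share x per-patient annual cost`` summed over treatments, and
the budget impact of introducing or removing a drug is the pairwise
difference between scenario budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError

__all__ = [
    "TREATMENTS",
    "PopulationProjection",
    "MarketShareScenario",
    "TreatmentCostSet",
    "eligible_population",
    "scenario_cost",
    "budget_series",
    "scenario_impact",
    "bia_report",
]

#: Anticoagulant options in the budget-impact market.
TREATMENTS: tuple[str, ...] = ("warfarin", "apixaban", "rivaroxaban", "lmwh")

#: Printed market shares carry two decimals; allow that much rounding slack.
_SHARE_SUM_TOL = 0.02


@dataclass
class PopulationProjection:
    """Yearly national population and eligible NVAF patients."""

    national: dict[int, int]
    eligible: dict[int, int]

    def __post_init__(self):
        years = sorted(self.national)
        if years != list(range(years[0], years[-1] + 1)):
            raise SchemaError("projection years must be contiguous")
        if sorted(self.eligible) != years:
            raise SchemaError("national and eligible series must cover the same years")
        for y in years:
            if self.national[y] <= 0 or self.eligible[y] <= 0:
                raise InvalidParameterError(f"populations must be positive in {y}")
            if self.eligible[y] > self.national[y]:
                raise InvalidParameterError(f"eligible exceeds national population in {y}")

    @property
    def years(self) -> list[int]:
        return sorted(self.national)

    @property
    def implied_fraction(self) -> float:
        """Eligibility fraction implied by the first projection year."""
        y0 = self.years[0]
        return self.eligible[y0] / self.national[y0]

    @classmethod
    def from_fraction(cls, national: Mapping[int, int], fraction: float) -> "PopulationProjection":
        eligible = {y: eligible_population(n, fraction) for y, n in national.items()}
        return cls(dict(national), eligible)


@dataclass
class MarketShareScenario:
    """Yearly treatment market shares for one scenario."""

    scenario_id: str
    shares: dict[int, dict[str, float]]  # year -> treatment -> fraction

    def __post_init__(self):
        for year, row in self.shares.items():
            for t, s in row.items():
                if not (0.0 <= s <= 1.0):
                    raise InvalidParameterError(
                        f"{self.scenario_id}/{year}: share of {t} is {s}, outside [0, 1]"
                    )
            total = sum(row.values())
            if abs(total - 1.0) > _SHARE_SUM_TOL:
                raise InvalidParameterError(
                    f"{self.scenario_id}/{year}: shares sum to {total:.3f}, expected 1 "
                    f"(±{_SHARE_SUM_TOL} for printed rounding)"
                )

    @property
    def years(self) -> list[int]:
        return sorted(self.shares)


@dataclass(frozen=True)
class TreatmentCostSet:
    """Per-patient annual treatment-plus-event cost by treatment (USD/year)."""

    costs: Mapping[str, float]

    def __post_init__(self):
        for t, c in self.costs.items():
            if c < 0:
                raise InvalidParameterError(f"annual cost of {t} must be non-negative, got {c}")

    def __getitem__(self, treatment: str) -> float:
        return self.costs[treatment]


def eligible_population(national: float, fraction: float) -> int:
    """Eligible patient count: national population x prevalence fraction, rounded."""
    if not (0.0 <= fraction <= 1.0):
        raise InvalidParameterError(f"fraction must lie in [0, 1], got {fraction}")
    return int(round(national * fraction))


def scenario_cost(
    patients: float,
    shares: Mapping[str, float],
    costs: TreatmentCostSet,
) -> float:
    """Yearly budget: sum over treatments of patients x share x annual cost."""
    total = 0.0
    for treatment, share in shares.items():
        if share > 0:
            if treatment not in costs.costs:
                raise SchemaError(
                    f"no annual cost for treatment {treatment!r} with share {share}"
                )
            total += patients * share * costs[treatment]
    return total


def budget_series(
    projection: PopulationProjection,
    scenario: MarketShareScenario,
    costs: TreatmentCostSet,
) -> dict[int, float]:
    """Yearly budgets of one scenario over the projection horizon."""
    if scenario.years != projection.years:
        raise SchemaError(
            f"scenario {scenario.scenario_id!r} years {scenario.years} do not match "
            f"projection years {projection.years}"
        )
    return {
        y: scenario_cost(projection.eligible[y], scenario.shares[y], costs)
        for y in projection.years
    }


def scenario_impact(a: Mapping[int, float], b: Mapping[int, float]) -> dict[int, float]:
    """Element-wise budget difference ``a - b`` over a common year set."""
    if sorted(a) != sorted(b):
        raise SchemaError(f"year sets differ: {sorted(a)} vs {sorted(b)}")
    return {y: a[y] - b[y] for y in sorted(a)}


def bia_report(
    projection: PopulationProjection,
    scenarios: Mapping[str, MarketShareScenario],
    costs: TreatmentCostSet,
    impact_pairs: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Budget table: one column per year; population, budgets and impacts.

    ``impact_pairs`` lists ``(minuend, subtrahend)`` scenario ids; each adds
    an ``impact_<minuend>_minus_<subtrahend>`` row so the differencing
    direction is explicit in the output.
    """
    years = projection.years
    budgets = {sid: budget_series(projection, sc, costs) for sid, sc in scenarios.items()}
    rows: dict[str, list[float]] = {
        "national_population": [projection.national[y] for y in years],
        "eligible_patients": [projection.eligible[y] for y in years],
    }
    for sid in scenarios:
        rows[f"budget_{sid}"] = [budgets[sid][y] for y in years]
    for a, b in impact_pairs:
        diff = scenario_impact(budgets[a], budgets[b])
        rows[f"impact_{a}_minus_{b}"] = [diff[y] for y in years]
    return pd.DataFrame(rows, index=pd.Index(years, name="year")).T
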