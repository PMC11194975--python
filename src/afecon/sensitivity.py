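"""Deterministic (tornado) and probabilistic sensitivity analysis.

DSA perturbs one parameter at a time — costs by ±20%, probabilities and
utilities by ±10% (clamped to their domain) — and records the ICER swing
for a chosen strategy pair. PSA samples every uncertain parameter from a
parametric distribution (beta for probabilities/utilities, gamma for
costs, lognormal for per-patient-year rates), re-evaluates all strategies
per iteration, and summarises cost-effectiveness probabilities and the
acceptability curve (CEAC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import ModelBundle, StrategyEngine, evaluate_strategy
from .errors import DegenerateParameterError, DistributionFitError, InvalidParameterError
from .states import EVENTS, STATE_ORDER, HealthState

__all__ = [
    "Z95_WIDTH",
    "DSASpec",
    "TornadoEntry",
    "PSADistribution",
    "PSAResult",
    "CEACCurve",
    "make_dsa_specs",
    "dsa_one_way",
    "tornado",
    "ci_to_distribution",
    "distribution_from_moments",
    "default_psa_distributions",
    "run_psa",
    "ce_probability",
    "ceac",
]

#: Width of a normal 95% interval in standard deviations (2 x 1.959964).
Z95_WIDTH = 3.919928

_AF = HealthState.AF.value
_DEAD = HealthState.DEAD.value


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSASpec:
    """One-way perturbation range for a single parameter."""

    param_id: str
    base: float
    low: float
    high: float
    category: str  # cost | probability | utility

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise InvalidParameterError(
                f"{self.param_id}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """ICER of the comparison with one parameter at its low / high value."""

    param_id: str
    icer_at_low: float | None
    icer_at_high: float | None

    @property
    def swing(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return math.inf
        return abs(self.icer_at_high - self.icer_at_low)


def make_dsa_specs(
    bundle: ModelBundle,
    cost_fraction: float = 0.20,
    other_fraction: float = 0.10,
) -> list[DSASpec]:
    """Build DSA ranges for every tunable parameter.

    Costs vary by ±20%; probabilities/rates and utilities by ±10%.
    Fractions (fatality, utility) are clamped to their [0, 1] domain after
    perturbation.
    """
    specs = []
    for pid, base, category in bundle.parameter_items():
        frac = cost_fraction if category == "cost" else other_fraction
        low, high = base * (1 - frac), base * (1 + frac)
        if category == "utility" or pid.startswith("fatality:"):
            low, high = max(0.0, low), min(1.0, high)
        specs.append(DSASpec(pid, base, low, high, category))
    return specs


def _pairwise_icer(bundle: ModelBundle, comparison: tuple[str, str]) -> float | None:
    """ICER of comparison[0] versus comparison[1] under the bundle."""
    a, b = comparison
    oa = evaluate_strategy(bundle, a)
    ob = evaluate_strategy(bundle, b)
    dq = oa.total_qaly - ob.total_qaly
    if dq == 0.0:
        return None
    return (oa.total_cost - ob.total_cost) / dq


def dsa_one_way(
    bundle: ModelBundle,
    spec: DSASpec,
    comparison: tuple[str, str],
) -> TornadoEntry:
    """Re-run the base case with one parameter at its low and high values."""
    try:
        icer_low = _pairwise_icer(bundle.set(spec.param_id, spec.low), comparison)
        icer_high = _pairwise_icer(bundle.set(spec.param_id, spec.high), comparison)
    except DegenerateParameterError as exc:
        raise DegenerateParameterError(
            exc.state, exc.total,
            f"perturbing {spec.param_id!r}: {exc}",
        ) from exc
    return TornadoEntry(spec.param_id, icer_low, icer_high)


def tornado(
    bundle: ModelBundle,
    comparison: tuple[str, str],
    specs: Sequence[DSASpec] | None = None,
    top: int = 10,
) -> list[TornadoEntry]:
    """One-way DSA over all (or given) parameters, sorted by descending swing."""
    if specs is None:
        specs = make_dsa_specs(bundle)
    entries = [dsa_one_way(bundle, s, comparison) for s in specs]
    entries.sort(key=lambda e: (-e.swing if math.isfinite(e.swing) else -math.inf, e.param_id))
    return entries[:top]


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.param_id for e in entries],
            "icer_low": [e.icer_at_low for e in entries],
            "icer_high": [e.icer_at_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# parametric distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSADistribution:
    """A sampling distribution for one parameter.

    families: ``beta`` (alpha, beta), ``gamma`` (shape, scale),
    ``lognormal`` (mu, sigma of log), ``point`` (value).
    """

    param_id: str
    family: str
    params: tuple[float, ...]

    @property
    def mean(self) -> float:
        f, p = self.family, self.params
        if f == "beta":
            return p[0] / (p[0] + p[1])
        if f == "gamma":
            return p[0] * p[1]
        if f == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if f == "point":
            return p[0]
        raise InvalidParameterError(f"unknown family {f!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        f, p = self.family, self.params
        if f == "beta":
            return rng.beta(p[0], p[1], size)
        if f == "gamma":
            return rng.gamma(p[0], p[1], size)
        if f == "lognormal":
            return rng.lognormal(p[0], p[1], size)
        if f == "point":
            return np.full(size, p[0])
        raise InvalidParameterError(f"unknown family {f!r}")


def distribution_from_moments(
    mean: float, sd: float, family: str, param_id: str = ""
) -> PSADistribution:
    """Method-of-moments fit of a named family to (mean, sd)."""
    if sd < 0 or not math.isfinite(mean):
        raise InvalidParameterError(f"{param_id}: invalid moments ({mean}, {sd})")
    if sd == 0.0:
        return PSADistribution(param_id, "point", (mean,))
    var = sd * sd
    if family == "beta":
        if not (0.0 < mean < 1.0):
            raise DistributionFitError(f"{param_id}: beta needs mean in (0,1), got {mean}")
        if var >= mean * (1.0 - mean):
            raise DistributionFitError(
                f"{param_id}: variance {var:.4g} >= m(1-m); beta method-of-moments "
                "infeasible — consider a lognormal family instead"
            )
        k = mean * (1.0 - mean) / var - 1.0
        return PSADistribution(param_id, "beta", (mean * k, (1.0 - mean) * k))
    if family == "gamma":
        if mean <= 0:
            raise DistributionFitError(f"{param_id}: gamma needs mean > 0, got {mean}")
        return PSADistribution(param_id, "gamma", (mean * mean / var, var / mean))
    if family == "lognormal":
        if mean <= 0:
            raise DistributionFitError(f"{param_id}: lognormal needs mean > 0, got {mean}")
        sigma2 = math.log1p(var / (mean * mean))
        mu = math.log(mean) - sigma2 / 2.0
        return PSADistribution(param_id, "lognormal", (mu, math.sqrt(sigma2)))
    raise InvalidParameterError(f"unknown family {family!r}")


def ci_to_distribution(
    mean: float,
    ci_low: float,
    ci_high: float,
    family: str,
    param_id: str = "",
) -> PSADistribution:
    """Fit a distribution to a mean and normal-approximate 95% CI.

    The standard deviation is recovered as ``(ci_high - ci_low) / 3.919928``
    and the family fitted by method of moments.
    """
    if not ci_low < ci_high:
        raise InvalidParameterError(
            f"{param_id}: need ci_low < ci_high, got ({ci_low}, {ci_high})"
        )
    if not (ci_low < mean < ci_high):
        # published tables occasionally print a mean outside its CI; the
        # moment fit needs only (mean, sd), so proceed with a warning.
        warnings.warn(
            f"{param_id}: mean {mean} outside CI ({ci_low}, {ci_high})", stacklevel=2
        )
    sd = (ci_high - ci_low) / Z95_WIDTH
    return distribution_from_moments(mean, sd, family, param_id)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def default_psa_distributions(
    bundle: ModelBundle,
    cost_cv: float = 0.10,
    utility_sd: float = 0.05,
) -> list[PSADistribution]:
    """Default PSA parameterisation of a bundle.

    On-treatment event rates get lognormal distributions fitted to their
    published 95% CIs; per-cycle and one-off costs get gamma distributions
    with coefficient of variation ``cost_cv``; utilities get beta
    distributions with absolute standard deviation ``utility_sd``.
    Sampling order follows the returned list order.

    When two strategies print the *same* rate entry (identical mean and
    CI — a single sourced parameter used by both arms), it is treated as
    one shared parameter: one draw applied to every strategy carrying it.
    Distinct parameters are always sampled independently.
    """
    dists: list[PSADistribution] = []
    seen: dict[tuple, str] = {}
    for strategy in bundle.strategies:
        for e in EVENTS:
            er = bundle.rates[(strategy, e)]
            key = (e, er.mean, er.ci_low, er.ci_high)
            if key in seen:
                continue  # identical printed entry: shared draw
            seen[key] = strategy
            others = [
                s for s in bundle.strategies
                if s != strategy and bundle.rates[(s, e)] == er
            ]
            pid = (f"rate:{'+'.join([strategy, *others])}:{e}" if others
                   else f"rate:{strategy}:{e}")
            dists.append(
                ci_to_distribution(er.mean, er.ci_low, er.ci_high, "lognormal", pid)
            )
    for strategy in bundle.strategies:
        m = bundle.values[strategy].per_cycle_cost(_AF)
        dists.append(distribution_from_moments(m, cost_cv * m, "gamma",
                                               f"treatment_cost:{strategy}"))
    first = bundle.values[bundle.strategies[0]]
    for state in STATE_ORDER:
        if state in (_AF, _DEAD):
            continue
        m = first.per_cycle_cost(state)
        if m > 0:
            dists.append(distribution_from_moments(m, cost_cv * m, "gamma",
                                                   f"state_cost:{state}"))
        ec = first.event_cost.get(state, 0.0)
        if ec > 0:
            dists.append(distribution_from_moments(ec, cost_cv * ec, "gamma",
                                                   f"event_cost:{state}"))
    for state in STATE_ORDER:
        if state == _DEAD:
            continue
        u = first.utility[state]
        dists.append(distribution_from_moments(u, utility_sd, "beta", f"utility:{state}"))
    return dists


@dataclass
class PSAResult:
    """Per-iteration per-strategy discounted (cost, QALY) pairs."""

    strategies: list[str]
    costs: np.ndarray   # (n_iter, n_strategies)
    qalys: np.ndarray   # (n_iter, n_strategies)
    seed: int
    param_ids: list[str] = field(default_factory=list)

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]

    def deltas(self, comparison: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
        """(delta_cost, delta_qaly) arrays for strategy a minus strategy b."""
        a, b = (self.strategies.index(s) for s in comparison)
        return self.costs[:, a] - self.costs[:, b], self.qalys[:, a] - self.qalys[:, b]

    def scatter_frame(self, comparison: tuple[str, str]) -> pd.DataFrame:
        dc, dq = self.deltas(comparison)
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iter),
                "comparison": f"{comparison[0]}_vs_{comparison[1]}",
                "d_cost": dc,
                "d_qaly": dq,
            }
        )


def _engine_setter(engines: Mapping[str, StrategyEngine], param_id: str) -> Callable[[float], None]:
    """Compile a parameter id into a writer on the engines' arrays."""
    kind, _, rest = param_id.partition(":")
    state_idx = {s: i for i, s in enumerate(STATE_ORDER)}
    event_idx = {e: i for i, e in enumerate(EVENTS)}
    if kind == "rate":
        strategy, _, event = rest.partition(":")
        # "a+b" strategy field = one shared parameter applied to several arms
        engs = [engines[s] for s in strategy.split("+")]
        j = event_idx[event]

        def setter(v: float) -> None:
            for eng in engs:
                eng.event_rates[j] = v
    elif kind == "untreated_rate":
        j = event_idx[rest]

        def setter(v: float) -> None:
            for eng in engines.values():
                eng.untreated_rates[j] = v
    elif kind == "fatality":
        j = event_idx[rest]

        def setter(v: float) -> None:
            for eng in engines.values():
                eng.fatality[j] = v
    elif kind == "disc_rate":

        def setter(v: float) -> None:
            for eng in engines.values():
                eng.disc_rate = v
    elif kind == "treatment_cost":
        eng = engines[rest]

        def setter(v: float) -> None:
            eng.recurring_cost[0] = v
    elif kind == "state_cost":
        j = state_idx[rest]

        def setter(v: float) -> None:
            for eng in engines.values():
                eng.recurring_cost[j] = v
    elif kind == "event_cost":
        j = state_idx[rest]

        def setter(v: float) -> None:
            for eng in engines.values():
                eng.event_cost[j] = v
    elif kind == "utility":
        j = state_idx[rest]

        def setter(v: float) -> None:
            for eng in engines.values():
                eng.utility[j] = v
    else:
        raise KeyError(param_id)
    return setter


def run_psa(
    bundle: ModelBundle,
    distributions: Sequence[PSADistribution] | None = None,
    n_iter: int = 5000,
    seed: int = 0,
    max_reject_fraction: float = 0.01,
) -> PSAResult:
    """Monte Carlo PSA: sample, rebuild, re-evaluate every strategy.

    All parameters are drawn independently with a single seeded generator;
    draws are taken distribution-by-distribution in list order (vector of
    ``n_iter`` values each), making results bit-reproducible for a given
    seed. Iterations whose sampled parameters over-fill a matrix row are
    recorded as NaN; more than ``max_reject_fraction`` of them aborts.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    if distributions is None:
        distributions = default_psa_distributions(bundle)
    rng = np.random.default_rng(seed)
    samples = np.column_stack([d.sample(rng, n_iter) for d in distributions])

    engines = {s: StrategyEngine(bundle, s) for s in bundle.strategies}
    setters = [_engine_setter(engines, d.param_id) for d in distributions]

    k = len(engines)
    costs = np.empty((n_iter, k))
    qalys = np.empty((n_iter, k))
    rejected = 0
    for i in range(n_iter):
        row = samples[i]
        for setter, v in zip(setters, row):
            setter(v)
        try:
            for j, s in enumerate(bundle.strategies):
                out = engines[s].evaluate()
                costs[i, j] = out.total_cost
                qalys[i, j] = out.total_qaly
        except DegenerateParameterError:
            costs[i] = np.nan
            qalys[i] = np.nan
            rejected += 1
    if rejected > max_reject_fraction * n_iter:
        raise DegenerateParameterError(
            "PSA", rejected / n_iter,
            f"{rejected}/{n_iter} PSA iterations produced degenerate matrices; "
            "check rate distributions against the cycle length",
        )
    return PSAResult(
        strategies=list(bundle.strategies),
        costs=costs,
        qalys=qalys,
        seed=seed,
        param_ids=[d.param_id for d in distributions],
    )


def ce_probability(
    psa: PSAResult, comparison: tuple[str, str], threshold: float
) -> float:
    """Fraction of iterations where comparison[0] has positive incremental NMB."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be non-negative")
    dc, dq = psa.deltas(comparison)
    ok = ~np.isnan(dc)
    if math.isinf(threshold):
        return float(np.mean(dq[ok] > 0))
    return float(np.mean(threshold * dq[ok] - dc[ok] > 0))


@dataclass
class CEACCurve:
    """Probability each strategy has the highest NMB, per threshold."""

    thresholds: np.ndarray
    strategies: list[str]
    probabilities: np.ndarray  # (n_thresholds, n_strategies)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.thresholds):
            for j, s in enumerate(self.strategies):
                rows.append(
                    {"threshold": float(lam), "strategy": s,
                     "probability": float(self.probabilities[i, j])}
                )
        return pd.DataFrame(rows)


def ceac(psa: PSAResult, thresholds: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curve; NMB ties split equally."""
    thresholds = np.asarray(thresholds, dtype=float)
    ok = ~np.isnan(psa.costs[:, 0])
    costs, qalys = psa.costs[ok], psa.qalys[ok]
    n, k = costs.shape
    probs = np.empty((thresholds.size, k))
    for i, lam in enumerate(thresholds):
        benefit = lam * qalys - costs
        best = benefit.max(axis=1, keepdims=True)
        winners = benefit == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    return CEACCurve(thresholds, list(psa.strategies), probs)
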