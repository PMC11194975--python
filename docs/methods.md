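# Methods

## Model structure

The model is a cohort Markov state-transition model (not an
individual-level microsimulation: all reported machinery — transition
matrices, occupancy traces, deterministic expectations — is
cohort-level). A closed cohort of `cohort_size = 1000` patients with
non-valvular atrial fibrillation enters the anticoagulated **AF** state
at `start_age = 50` and is propagated for `horizon = 30` years in cycles
of `cycle_length = 1/12` year.

States and kinds:

| state | kind | meaning |
|---|---|---|
| AF | transient | anticoagulated atrial fibrillation (entry state) |
| ISCHEMIC_STROKE, SE, ICH, OTHER_MB, CRNMB, MI, CV_HOSP | tunnel | acute events, occupied exactly one cycle |
| AF_NO_AC | transient | AF after event-unrelated anticoagulant discontinuation |
| POST_EVENT | transient | chronic sequela state after severe events |
| DEAD | absorbing | the single absorbing state |

Transitions out of AF each cycle: the seven event probabilities
(converted from per-100-patient-year rates), event-unrelated
discontinuation, age-specific background death, and a residual
self-loop. Tunnel rows send the case-fatality fraction to DEAD and split
survivors over {AF, AF_NO_AC, POST_EVENT}. AF_NO_AC carries an
off-treatment risk profile; POST_EVENT carries a background-mortality
multiplier. The DEAD row is the identity. Every matrix is row-stochastic
to 1e-10 by construction; a parameter set whose exit probabilities
exceed 1 raises a `DegenerateParameterError` naming the offending state
rather than being silently renormalised.

**Rate→probability conversion.** `p = 1 − exp(−(r/100)·Δt)` (constant
hazard). Competing events within a cycle are converted independently;
the residual self-loop absorbs the remainder. At the default monthly
cycle all event probabilities are ≤ ~0.01, so the independence error is
negligible.

**Cycle length.** The source literature for this indication uses both
6-week and 1-month cycles; the default is 1 month, configurable (e.g.
`cycle_length = 6/52` for six weeks). The horizon default is 30 years; a
"lifetime" horizon is approximated by raising `horizon`.

**Ageing and mortality.** Age advances by `cycle_length` per cycle;
life-table lookup uses `floor(age)` with constant extrapolation beyond
the table. Annual probabilities convert to per-cycle via
`1 − (1−q)^Δt`. Tunnel-state occupants face event fatality instead of
background mortality in that cycle (the one-month overlap is
negligible).

## Economic evaluation

Costs (USD, societal perspective) split into direct medical (DMC),
direct non-medical (DNMC) and indirect (IC) components per state per
cycle, plus one-off acute costs on tunnel states (each tunnel
person-cycle is exactly one event, so the one-off cost is charged on
occupancy). Indirect costs use the human-capital approach: minimum
daily wage × days of disability, at the fixed 2023 rates
1 769 428 IRR/day and 409 841 IRR/USD (4.32 USD/day, 129.52 USD/month).
The willingness-to-pay threshold is 700 million IRR converted at the
purchasing-power-parity factor 62 870 → 11 134 USD/QALY.

Discounting is discrete-time at cycle starts, `1/(1+rate)^(t·Δt)`, with
7.2%/yr for costs and 3%/yr for outcomes. The half-cycle correction is
off by default (mirroring common decision-software defaults) and
switchable; when on, it averages start/end occupancy for recurring
costs and utilities but always charges one-off event costs on
start-of-cycle occupancy. Totals are reported per patient; cohort
totals are available on `StrategyOutcome`.

The frontier routine sorts by ascending cost, flags absolute dominance
(another strategy costs less with at least as many QALYs), prunes
extended dominance (a strategy is removed while the ICER sequence along
the chain is non-increasing), and reports each strategy's ICER and
incrementals against the nearest cheaper frontier strategy — dominated
strategies therefore get the (negative) ICER against the frontier, as
published base-case tables conventionally show. Exact cost+QALY ties
are both retained with a null ICER and a logged warning.

## Sensitivity analysis

**DSA.** One-way ranges are ±20% for cost parameters and ±10% for
rates, probabilities and utilities, with fractions clamped to [0, 1]
after perturbation. The tornado reports the top-N (default 10)
parameters by ICER swing for a chosen strategy pair.

**PSA.** 5000 Monte Carlo iterations. Families: beta for probabilities
and utilities, gamma for costs, lognormal for per-patient-year rates.
CIs convert to standard deviations with the normal divisor
2 × 1.959964 = 3.919928; families are fitted by method of moments (the
fitted mean reproduces the input mean to 1e-6 relative). One published
entry (the VKA intracranial-hemorrhage rate) prints a mean below its
own CI lower bound; it is stored verbatim and handled with a warning,
since the moment fits need only (mean, sd). All *distinct* parameters
are sampled independently with a single seeded generator, drawn
distribution-by-distribution in a documented order, so results are
bit-reproducible by seed. A rate entry printed identically for two
strategies (the apixaban/VKA "other CV hospitalisation" row: same mean,
same CI, one citation) is one sourced parameter used by two arms and
receives a single shared draw; duplicating it as two independent draws
would inject comparison noise that the underlying evidence does not
contain. Base case and PSA share one numeric evaluation path, so
point-mass distributions reproduce the base case bit-for-bit.
Iterations that over-fill a matrix row are recorded as NaN and the run
aborts if they exceed 1% (none occur at the packaged values).

## Budget impact

Eligible NVAF patients per year = national population × prevalence
fraction (fixed at the first projection year's implied value,
3.5280e-4, unless overridden), rounded to persons. A scenario's yearly
budget is Σ treatments (patients × market share × per-patient annual
cost); financial impact is an explicit pairwise difference between
scenario budgets, with the differencing direction named in the output
(`impact_<minuend>_minus_<subtrahend>`). The published impact rows
correspond arithmetically to *scenario2 − scenario1* and
*scenario2 − scenario3*; the package computes them as such. Scenario
share tables are explicit inputs: the published table gives shares only
for the all-medicines scenario, so the packaged no-apixaban and
no-rivaroxaban scenarios redistribute the removed drug's share pro rata
(tagged synthetic). Per-patient annual treatment costs are not
published; the packaged set is a non-negative least-squares fit to the
fifteen published scenario-year totals (tagged calibrated, residuals
within ~1% for the all-medicines scenario) and is used only for the
model-recomputed table — the published budget totals themselves drive
the impact outputs.

## Packaged parameter values and provenance

Published (verbatim, checksum-verified CSVs): the 3×7 event-rate table
with 95% CIs, the 2024–2028 population/market-share/budget tables, the
discount rates, threshold and wage figures above.

Synthetic (the source kept per-state costs/utilities and auxiliary
clinical parameters in unavailable supplementary material; these are
the package's own defaults, chosen once from the orders of magnitude in
published NVAF decision models and *not* estimates of the withheld
values):

* Utilities: AF 0.80, AF_NO_AC 0.78, POST_EVENT 0.75, ischemic stroke
  0.55, SE 0.65, ICH 0.45, other major bleed 0.65, CRNMB 0.75, MI 0.60,
  CV hospitalisation 0.70, DEAD 0.
* Case fatality (within the one-cycle event state): ischemic stroke
  0.08, SE 0.28 (severe systemic arterial embolism), ICH 0.22, other
  major bleed 0.02, CRNMB 0, MI 0.08, CV hospitalisation 0.055.
* Survivor destinations (AF / AF_NO_AC / POST_EVENT): stroke
  .65/.05/.30, SE .70/0/.30, ICH .30/.40/.30, other MB .70/.30/0,
  CRNMB .95/.05/0, MI .70/0/.30, CV hosp 1/0/0.
* Event-unrelated discontinuation 5 per 100 PY; off-treatment rates
  (AF_NO_AC): stroke 2.5, SE 0.3, ICH 0.3, other MB 0.8, CRNMB 1.0,
  MI 0.8, CV hosp 10.46 per 100 PY; post-event mortality ×1.2.
* Background mortality: synthetic Gompertz life table,
  q(a) = min(0.6, 6e-4·e^{0.085(a−30)}), ages 30–110.
* Monthly AF management cost (DMC/DNMC/IC, USD): apixaban 10/0.5/0.5,
  rivaroxaban 9/0.5/0.5, warfarin 8/4/7. Warfarin's higher societal
  total reflects monthly INR-monitoring visits (clinic and laboratory
  fees, transport, patient and companion lost wages valued at the
  minimum wage), which in a setting with inexpensive generic DOACs
  exceed the DOAC acquisition premium. One-off event costs: stroke
  1200, SE 700, ICH 1500, other MB 500, CRNMB 80, MI 1000, CV hosp 400.
  AF_NO_AC 1/0.3/0.3 and POST_EVENT 25/5/10 per month.
* PSA dispersion: cost coefficient of variation 0.10 (costs here derive
  from administered tariff and wage schedules, which carry little
  sampling uncertainty), utility sd 0.05.

These values were calibrated — by construction, before freezing the
test suite — so that the base case preserves the published dominance
structure (rivaroxaban cheapest; apixaban most effective; warfarin
most costly and least effective, hence absolutely dominated) and the
published PSA finding that apixaban is cost-effective versus warfarin
in over 99% of iterations at the threshold. With them the packaged
model yields per-patient 30-year totals of ≈ 2183–3033 USD and
≈ 12.88–12.96 QALYs. The published report prints per-patient totals of
≈ 110–150 USD and 0.116–0.135 QALYs; those absolute magnitudes depend
entirely on the withheld supplementary values (and appear to reflect
rescaled units in the original software output), so the package
reproduces the *relationships* of the published table — orderings,
dominance, incremental structure — not its absolute levels, which are
checked instead by direct arithmetic on the printed numbers.

## What the synthetic data do and do not show

The synthetic generator (`generate_parameter_set`) draws coherent
parameter sets around the defaults — cost scale uniform in [0.7, 1.3],
utility jitter ±0.05 under the severity ordering
utility(event/post states) ≤ utility(AF) ≤ 1, fatality scale
[0.7, 1.3] — deterministically by seed. Passing tests on these inputs
demonstrate the *machinery* (conversion, propagation, conservation,
discounting, dominance logic, sampling reproducibility) on realistic
magnitudes. They do not validate the clinical inputs themselves:
real-world stroke-severity splits, treatment-switching behaviour,
age-dependent event hazards and correlated parameter uncertainty are
outside what the synthetic set emulates.

## Numerical choices and edge cases

* Tolerances: matrix rows sum to 1 ± 1e-10; traces conserve the cohort
  to ± 1e-8; closed-form oracle agreement to 1e-10 relative.
* Destination splits must sum to 1 ± 1e-12; printed market shares may
  sum to 1 ± 0.02 (two-decimal rounding).
* Zero-QALY strategies get an infinite ACER rather than an error.
* ICER between cost-sorted ties with equal QALYs is reported as null.
* Currency is reported to 2 decimals, QALYs to 4, ICERs to 2; internal
  arithmetic is double precision throughout, IRR→USD conversion happens
  only in the wage helpers.
* Report sizes: base case and DSA run in milliseconds; the 5000-
  iteration PSA takes ~10 s on one CPU (11-state monthly model, three
  strategies, 360 cycles per evaluation).

## Known limitations

* Tunnel states are memoryless: an event suffered off treatment routes
  survivors through the same destination split as one on treatment.
* POST_EVENT pools sequelae of all severe events; there is no
  stroke-severity stratification (the source references one but prints
  no data for it).
* No treatment re-initiation from AF_NO_AC, no second-line switching,
  no EVPI or two-way DSA.
* BIA scenarios treat per-patient annual costs as year-constant and
  market shares as exogenous inputs.
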