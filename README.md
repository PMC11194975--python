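# afecon

Cost-utility and budget-impact modelling of oral anticoagulants —
apixaban, rivaroxaban and warfarin (VKA) — for stroke prevention in
non-valvular atrial fibrillation (NVAF), parameterised for the Iranian
healthcare setting and a societal costing perspective.

The package is aimed at health-economics analysts and methodologists who
want a programmable, testable implementation of the standard decision-
analytic toolchain for this indication: a cohort Markov state-transition
model, incremental cost-effectiveness analysis with dominance handling,
deterministic (tornado) and probabilistic (Monte Carlo) sensitivity
analysis, and a multi-year budget-impact model over market-share
scenarios.

## The model

A closed cohort of 1000 NVAF patients enters at age 50 in the
anticoagulated **AF** state and is propagated in monthly cycles over a
30-year horizon through eleven health states: AF, seven single-cycle
*tunnel* states for acute events (ischemic stroke, systemic embolism,
intracranial hemorrhage, other major bleeding, clinically relevant
non-major bleeding, myocardial infarction, other cardiovascular
hospitalisation), AF without anticoagulation (event-unrelated
discontinuation), a chronic post-event state, and death.

Published event rates *r* (events per 100 patient-years, with 95% CIs)
convert to per-cycle probabilities under a constant hazard:

    p = 1 − exp(−(r/100) · Δt),        Δt = cycle length in years.

Each strategy's discounted totals are

    Cost  = Σ_t (1+d_c)^(−tΔt) · n_t · c,
    QALY  = Σ_t (1+d_e)^(−tΔt) · n_t · u · Δt,

with occupancy row `n_t`, per-state costs `c` (direct medical, direct
non-medical and indirect components; human-capital indirect costing) and
utilities `u`, discounted at d_c = 7.2%/yr for costs and d_e = 3%/yr for
outcomes. Strategies are compared by ACER (cost/QALY), chained ICERs
(Δcost/ΔQALY) along the dominance-pruned frontier, and net monetary
benefit NMB(λ) = λ·QALY − cost at the willingness-to-pay threshold
λ = 11 134 USD/QALY (Iran's 2023 per-capita GDP at purchasing power
parity). PSA uses 5000 Monte Carlo iterations with beta distributions
for utilities, gamma for costs and lognormal for rates (method-of-
moments fits to means and 95% CIs).

The per-strategy event rates, budget-impact population/market-share/
budget tables and all headline thresholds are packaged verbatim from
their published source (provenance tag `published`); per-state costs,
utilities and auxiliary clinical parameters are coherent synthetic
defaults (`synthetic`), and the budget-impact treatment costs are
least-squares calibrated to the published totals (`calibrated`). See
`docs/methods.md` for every value and the reasoning behind it.

## Worked example

```bash
python examples/base_case.py
```

prints the base-case frontier on the packaged inputs:

```
   strategy  total_cost  total_qaly      icer  incr_cost  incr_qaly            dominance    acer
rivaroxaban     2182.57     12.9112       NaN        NaN        NaN          undominated 169.045
   apixaban     2199.08     12.9646    309.38      16.51     0.0534          undominated 169.623
        vka     3033.18     12.8846 -10427.80     834.10    -0.0800 absolutely_dominated 235.412
```

Rivaroxaban is the cheapest strategy; apixaban buys 0.0534 extra QALYs
per patient at 309 USD each; warfarin (vka) costs more *and* yields
fewer QALYs than apixaban, so the frontier flags it as absolutely
dominated — the same dominance structure as the published analysis.
`examples/sensitivity_analysis.py` adds the tornado and PSA (apixaban is
cost-effective versus warfarin in ≥ 99% of iterations at the threshold,
and apixaban-vs-rivaroxaban is a near toss-up), and
`examples/budget_impact.py` reproduces the published five-year
financial-impact rows, e.g. −6 413 654 USD in 2024 for the market mix
with apixaban versus without it.

The same analyses are scriptable from a shell:

```bash
afecon run-base  --out out/
afecon run-psa   --seed 1 --n-iter 5000 --out out/
afecon run-bia   --out out/
afecon gen-fixture --seed 7 --out-dir inputs/   # emit editable CSV inputs
afecon run-base --input-dir inputs/ --out out2/
```

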