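# Methods

## Model structure

A cohort of patients with unresectable hepatocellular carcinoma, not
candidates for ablation, resection, or transplantation, starts in the
**local** state and receives its first embolization session in cycle 1.
Cycles are 2 months; the horizon is 30 cycles (5 years). The clinical
states are local, TAE-eligible progressive, TAE-refractory progressive
(systemic therapy), decompensated cirrhosis, and death. Decompensated
cirrhosis exits only to death; death is absorbing. By assumption, the
local and TAE-eligible states share the same per-cycle transition
quadruple (the survival curves of the trial arms are applied while the
patient remains embolization-eligible), so progression out of the
TAE-eligible state leads to the refractory state with the same
probability that governs local-to-eligible progression.

## Transition probabilities

All hazards are treated as constant (exponential survival), so a median
time-to-event `m` maps to a per-cycle probability `1 − 0.5^(c/m)` for
cycle length `c` in the same units, and an annual probability `a` maps
to `1 − (1 − a)^(c/12)`. The progression-specific hazard is the PFS
hazard minus the OS hazard; if a user supplies a PFS median above the
OS median the difference is clamped to zero with a warning.

Competing risks within a cycle are ordered death → decompensation →
progression, each applied to the survivors of the previous risk. This
ordering reproduces the published per-cycle probabilities for every arm
and population to the printed two decimal places, with two caveats we
treat as printing artifacts: the DEB-TACE stay-probability is printed
as the complement of the *rounded* competing risks (84.10 instead of
the unrounded 84.09), and the refractory persistence is printed as
81.94 for one arm although the refractory state is arm-independent by
construction (both arms use the derived 81.92). The derived values are
canonical; `TransitionSet` exposes them at full floating precision and
reports round only for display.

Sources of the base-case inputs: the randomized trial comparing the two
therapies (OS/PFS medians, ITT and per-protocol), a systemic-therapy
trial (OS median 19.2 months), and cohort studies for the annual
decompensation rates (11.8% while TAE-eligible, 53.4% on systemic
therapy) and the 25% one-year survival of decompensated cirrhosis.

## Session accounting and costs

The single largest under-specification in reproducing this class of
model is *when* embolization sessions (and their admission costs) are
delivered. The engine therefore makes the policy explicit and
selectable:

- `per_cycle_while_eligible` (default): a session is delivered in every
  cycle spent in the local or TAE-eligible state until the arm's cap
  (2 TARE, 6 DEB-TACE) is exhausted.
- `on_entry`: sessions only in cycle 1 and on transition into the
  TAE-eligible state.

Session counters are tracked by expanding the two treatable states with
a sessions-delivered dimension; they affect cost accrual only, never
the transition probabilities.

Cost accrual per cycle, under the default toggles:

- treatment cycle: arm admission cost (DEB-TACE 845,320 JPY; TARE
  734,896 + 1,440,000 JPY microspheres, plus 36,000 + 22,215 JPY
  angiography/scintigraphy work-up on the first TARE session only),
  plus the 2-month outpatient cost (2 × 98,455 JPY) and one contrast-CT
  fee (30,000 JPY);
- non-treatment local/eligible cycle: outpatient cost only;
- refractory cycle: 2 × 1,242,800 JPY (atezolizumab + bevacizumab);
- decompensated cycle: 2 × 247,690 JPY; death: nothing.

The `ct_schedule` toggle (`treatment` | `every_cycle` | `follow_up` |
`none`) and `outpatient_in_treatment_cycles` flag expose the accrual
conventions. The defaults were calibrated once against the published
five-year totals: with the default combination the model reproduces all
five published cost figures (both arms, both populations, and both
ICERs) to the yen, which we take as strong evidence that this is the
convention of the original implementation. Rewards accrue at the start
of each cycle with that cycle's discount factor
`(1.02)^(−t·c/12)` (cycle 0 undiscounted); a half-cycle-correction
toggle (halving the first and last cycle) exists and defaults off, as
the exact reproduction is achieved without it.

The DEB-TACE admission cost is itself an output of the claims module:
with `n` selected admissions of which `k` had severe hepatobiliary
complications, the expected complication add-on is
`(k/n)(mean_comp − mean_no_comp)` and the weighted admission cost is
`mean_no_comp + add-on` (identically the plain mean of all selected
costs). With the published statistics (n = 6,986, k = 25, stratum means
839,223 and 2,543,046 JPY) this gives 6,097 and 845,320 JPY. The TARE
admission cost reuses the components assumed shared with DEB-TACE
(procedure fee 200,400, devices 71,800, per-diem 456,599, complication
add-on) and adds the microsphere price converted at 180 JPY/GBP.

## Utilities and outcomes

Utilities per year of occupancy: local 0.788, TAE-refractory 0.748,
TAE-eligible 0.768 (defined as the mean of the other two, exposed as
`derive_u_eligible`), decompensated 0.524, death 0. QALY accrual per
cycle is utility × 1/6 year. The incremental comparison reports ΔC,
ΔE, the ICER (undefined, not infinite, at ΔE = 0), net monetary
benefit, and dominance labels.

## Sensitivity analyses

One-way deterministic analysis varies each parameter to its bounds
(costs ±20%, utilities ±10%, survival medians and annual rates ±30%,
discount rate 0–4% absolute) with everything else at base; ranges follow
the itemized input table rather than the blanket ±10% the accompanying
text mentions for costs. Utility and rate upper bounds are clamped to
1. The one-time work-up and CT fees carry no published range and are
excluded from the tornado (they do participate in the probabilistic
analysis). Threshold values solve `ICER(θ) = WTP` with Brent's method
to 1e-6 relative tolerance, reported only when the ICER−WTP sign
changes across the scanned interval.

The probabilistic analysis draws every uncertain parameter per
iteration with sd = 10% of its mean — gamma (method of moments:
shape = (mean/sd)², scale = sd²/mean) for costs and survival medians,
beta (α = mν, β = (1−m)ν, ν = m(1−m)/sd² − 1) for utilities and annual
rates, triangular (0, 2%, 4%) for the discount rate. One draw per
physical parameter is shared across both arms within an iteration, so
the arms face the same economic environment; arm-specific medians are
distinct physical parameters. Survival-median draws propagate into the
transition probabilities. The acceptability curve is the fraction of
iterations with positive incremental net benefit at each
willingness-to-pay value.

## Synthetic claims generator

The generator emulates the structure of Japanese DPC-style admission
records: per-admission total cost drawn from a gamma distribution
within each complication stratum (published stratum means; coefficient
of variation 0.5 by default — the real dispersion is unpublished, and
0.5 is a typical right-skew for inpatient cost data), a severe
complication indicator at the published 25/6,986 prevalence implemented
by adding one procedure code from the complication list, and
age/sex fields matching the described cohort (74.86 ± 9.67 years,
5,196/6,986 male) that are generated for realism but unused
downstream. A contaminant fraction violates exactly one selection
criterion to exercise the filter. What passing tests show: the
selection and aggregation arithmetic is correct and unbiased at the
published cohort size. What they do not show: anything about real
claims data — coding practice, within-hospital correlation, cost
seasonality, or complication-cost dependence are not modelled.

## Numerical choices and limitations

- Probabilities are carried at full double precision; rounding to the
  printed two decimals happens only in reports and tests.
- Transition-matrix rows are validated to sum to 1 within 1e-12.
- The microsimulation (inverse-CDF sampling per cycle from the same
  matrix and reward vectors) is the independent oracle for the cohort
  engine; agreement is asserted within 3 Monte-Carlo standard errors at
  50,000 patients.
- Problem sizes used in the shipped analyses: 30-cycle cohort runs
  (exact), 10,000 PSA iterations, 50,000 microsimulation patients,
  200 synthetic claims cohorts of 6,986 admissions for parameter
  recovery.
- Limitations mirror the model's scope: no ablation/resection/
  transplantation pathways, no time-varying hazards or tunnel states
  beyond the session counter, no late-complication or adverse-event
  disutilities, and costs fixed at 2022 fee-schedule levels with fixed
  exchange rates (160 JPY/USD for display, 180 JPY/GBP for the
  microsphere price).
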