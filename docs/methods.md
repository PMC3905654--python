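# Methods

This note records the model's assumptions, the numerical conventions, the
design decisions taken where the structure was genuinely open, and what
the synthetic inputs do and do not emulate.

## Model structure and assumptions

The analysis compares two antipsychotic strategies for bipolar disorder
over a 5-year (complementary 10-year) horizon with annual cycles, from a
payer (MoH) and a societal perspective. The causal chain modelled is:
drug choice → first-year adverse events (EPS, significant weight gain) →
elevated long-term risk of four metabolic complications (diabetes,
hypertension, CHD, stroke) → costs, utility decrements and mortality.

Assumptions inherited from the model design:

* EPS and weight gain are independent events; weight gain is resolved once,
  in year 1, and its disutility and complication risk elevation are
  permanent.
* One treatment switch at most (EPS-triggered, to a third antipsychotic
  with an asenapine-like metabolic profile); no re-switching, no dose
  reduction, no non-adherence.
* At most one new complication per patient per year; complications never
  remit; risks are independent across complications (no
  diabetes-potentiates-CHD interaction).
* Death is absorbing; the dead accrue nothing beyond the one-time
  fatal-event cost in the cycle of death.
* Year 1 is governed entirely by the decision tree: complication states
  (including those prevalent at entry) begin to generate costs,
  disutilities and mortality from cycle 2, the year the cohort enters the
  Markov model.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| u_BPD | 0.800 | baseline utility; bounds 0.580–1.000 |
| du weight gain | 0.066 | permanent from acquisition |
| du EPS | 0.074 | applied for 0.25 year (3 months), year 1 only |
| w_additional | 0 | weight on non-worst concurrent complication disutilities; 0.5/1.0 are DSA scenarios |
| weight gain y1 | 39.2% / 55.1% | asenapine / olanzapine; bounds per published CIs |
| EPS y1 | 10.7% / 9.5% | asenapine / olanzapine |
| drug cost | $1,030 / $1,871 per year | CAD-2011; asenapine price has no interval and is held fixed |
| suicide multiplier | 15.5 | bounds 12.25–18.44; replaces the general-population suicide component |
| discount rate | 5%/year | costs and QALYs |
| p(switch \| EPS) | 0.20 | **assumption** (unpublished), ±25% in sensitivity |
| switch drug cost | $1,871 | **assumption** (set to olanzapine's) |
| p(fatal \| CHD), p(fatal \| stroke) | 0.10, 0.15 | **assumptions** (claims-derived originals unpublished) |
| sex mix | 0.50 male | varied in DSA |

Weight-gain odds ratios and complication mortality risks are per
complication and sex (see `base_case.yaml`); ORs act on the odds scale by
default (`or_as_rr` switches to risk-scale application), and mortality
risks combine multiplicatively across concomitant complications
(`mortality_combination: max` is the alternative), clipped at 1.

## Numerical conventions

* **Within-cycle ordering.** Death is resolved first; survivors face the
  complications as sequential competing events in the order diabetes,
  hypertension, CHD, stroke (configurable). Candidate *i* occurs with
  probability p_i·Π_{j<i}(1−p_j). At realistic incidences (≤3%/year) a
  permutation of this order moves incremental results by well under 1%
  (pinned by a test). One systematic consequence: a late-ranked low-OR
  candidate (stroke) is thinned slightly more in the weight-gained
  stratum, so per-complication occupancy dominance of the weight-gained
  stratum holds only up to ~1e-4 of mass; aggregate complication burden
  dominance is strict.
* **Discounting.** Factor 1/(1+r)^(t−1): year 1 undiscounted, the usual
  convention for annual-cycle models (`discount_first_year` shifts the
  stream one period). No half-cycle correction by default;
  `half_cycle_correction` applies trapezoid-style half weights to the
  first and last cycle.
* **Switch timing.** Switchers pay 6 months of each drug in year 1 (EPS
  events cluster early in treatment), and the switch drug thereafter.
* **Accrual timing.** Transitions resolve at the start of each Markov
  cycle; costs and utilities accrue over the post-transition state, so an
  incident event year is costed in the cycle it occurs and mass dying in a
  cycle accrues nothing that year (beyond the fatal-event charge). This is
  mirrored exactly in the microsimulation oracle.
* **Utility floor** at 0; disutility magnitudes are non-negative at base
  (a published interval crossing zero, e.g. hypertension in women, may
  produce a small negative decrement at a bound).
* **Fatal events** are charged once, in the cycle of death, at that
  cycle's discount factor, under both perspectives.
* `advance` returns the new cohort *and* the cycle's fatal-transition
  masses, which the accrual layer needs for one-time fatal costs.

## Sensitivity analyses

The DSA re-runs the full model once per parameter per bound (110 records
× 2 perspectives). Published intervals are used verbatim; parameters
without one get ±25% (probabilities clipped to [0,1]); a one-sided
interval is completed by the same rule.

The PSA interprets each interval as a central 95% interval and
quantile-matches: beta for probabilities and utilities (mean at base,
central width matched by solving for the concentration), gamma for costs
(mean at base; the width function is non-monotone in the shape at tiny
shapes, so the solver brackets from the width maximum), lognormal for
ratios (median at base, σ = (ln U − ln L)/3.92). Parameters are sampled
independently (no correlation structure is given); the intervention drug
price (no interval), w_additional (scenario values, not a CI), entry age
and the discount rate are held at base. One master seed spawns one
substream per parameter, so draws are independent of evaluation order and
exactly reproducible. Both perspectives are evaluated from the same
draws; the dominance fraction is the share of replications with ΔC<0 and
ΔQ>0.

## Synthetic inputs: what they emulate

The life table is Gompertz, q(a) = 1 − exp(−b·e^{c·a}), with per-sex
parameters chosen so 5-year all-cause mortality at 40 is below 2% and
male exceeds female — the shape and magnitude of a general-population
table, not any specific one. Suicide mortality is a small age-flat
per-sex component. Baseline epidemiology applies a seeded ±10% jitter
around mid-life general-population magnitudes (prevalences 1–15% at
entry, incidences 0.1–3%/year growing ~3%/year with age), with `low` /
`high` stress scales.

Consequences: structural results (dominance everywhere in the DSA, the
high PSA dominance fraction, the ~$3.8M 5-year payer savings per 1,000
patients, which are dominated by the drug-price difference) are robust to
the synthetic epidemiology; the *complication-driven* share of the QALY
gain is not — with different true incidences the incremental QALY number
moves materially. Passing tests therefore demonstrate the correctness of
the engine and the qualitative findings, not a calibration of Canadian
epidemiology.

## Validation

An individual-level microsimulation re-implements the identical event
logic by per-patient sampling (no matrix algebra) and must agree with the
cohort engine within 3 Monte Carlo standard errors at n = 50,000 on five
fixtures (base case, zero-risk, symmetric arms, high/low incidence).
Zero-risk outcomes reduce to closed-form discounted annuities
(0.800 × 4.5459505 = 3.6367604 QALYs/person over 5 years); symmetric arms
give exactly zero increments; a point-mass PSA reproduces the
deterministic base case bit-exactly.

## Problem sizes

The deterministic model is a 37-state × 6-stratum × 2-sex cohort over 5
or 10 cycles (~6 ms per evaluation). The shipped acceptance run uses the
full 10,000 PSA replications; the test suite uses 8–400 replications for
exactness/reproducibility/shape checks and 50,000 microsimulated patients
per fixture for oracle equivalence.

## Known limitations

* The switch probability, switch-drug price and fatal-event fractions are
  assumptions; results are exposed to them through the DSA/PSA rather
  than calibrated.
* No adherence/persistence modelling, no comorbidity interactions, no
  remission, no correlation in the PSA — all inherited from the model
  design.
* The half-cycle correction is the simple trapezoid variant.
* Productivity losses apply while a complication is present; no separate
  friction cost is charged for fatal events.
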