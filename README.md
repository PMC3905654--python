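# bipolarcua

A cost-utility model of atypical antipsychotic treatment in bipolar
disorder (BPD), comparing asenapine against olanzapine through the
metabolic consequences of treatment-induced weight gain.

The package is aimed at health-economics modellers: it is a complete,
testable re-implementation of a published-style decision-analytic model —
a one-year decision tree chained to an annual-cycle Markov cohort model —
with deterministic and probabilistic sensitivity analysis, an
individual-level microsimulation used as an internal validation oracle,
and synthetic generators for the external inputs (life tables,
epidemiology) so the whole pipeline runs from a single YAML file.

## The model

**Year 1 (decision tree).** Three events: an extrapyramidal-symptom (EPS)
event with probability `p_eps`, a switch to a third antipsychotic given
EPS (`p_switch|eps`), and significant (≥7%) weight gain (`p_wg`),
independent of EPS. The tree emits six strata (weight gain × EPS ×
switched) with year-1 costs (drug, EPS management) and QALYs
(`u_BPD − du_wg·1{wg} − du_eps·¼·1{eps}`).

**Years 2..T (Markov cohort model).** States are combinations of
diabetes, hypertension, CHD (none/event-year/post) and stroke
(none/event-year/post) plus absorbing death — 37 states. Each cycle:

1. death first, at the life-table rate with the general-population suicide
   component replaced by 15.5× that rate (the elevated BPD suicide risk),
   multiplied by the mortality risk of every complication present;
2. at most one new complication per survivor per year, resolved as
   sequential competing events; weight-gained strata face incidences
   raised on the odds scale, `p' = OR·p/(1−p) / (1 + OR·p/(1−p))`;
3. incident CHD/stroke split into fatal (one-time fatal-event cost) and
   non-fatal (an event year at higher cost, then a post tier).

QALYs weight each alive year by
`u = u_BPD − du_wg·1{wg} − [max_c du_c + w·Σ_{others} du_c]`, i.e. only
the most debilitating complication counts by default (`w = 0`). Costs are
accrued under a Ministry-of-Health perspective (drugs, EPS management,
direct complication costs) or a societal perspective (adding productivity
losses and informal care for stroke). Everything is discounted at 5%/year
and reported per 1,000 patients. The verdict is the incremental
cost-utility ratio ΔC/ΔQ, or *dominant* when ΔC < 0 and ΔQ > 0.

Clinical and cost inputs (adverse-event incidences, odds ratios,
mortality risks, utilities, CAD-2011 costs with their sensitivity bounds)
are shipped in `src/bipolarcua/data/base_case.yaml`; the config schema is
documented in `docs/config_schema.md`. Life tables and epidemiology are
synthetic stand-ins generated in-package (see `docs/methods.md`).

## Worked example

```sh
bipolarcua run --out results/
```

prints (base case, 5-year horizon):

```
Cost-utility results per 1,000 patients, 5-year horizon

MoH perspective
Strategy           Costs ($)   Incr. costs ($)     QALYs   Incr. QALYs   ICUR ($/QALY)
olanzapine        10,216,088        -3,773,765     3,399         48.21        dominant
asenapine          6,442,324                       3,447

Societal perspective
Strategy           Costs ($)   Incr. costs ($)     QALYs   Incr. QALYs   ICUR ($/QALY)
olanzapine        11,305,450        -3,789,131     3,399         48.21        dominant
asenapine          7,516,319                       3,447
```

Read: over five years, 1,000 asenapine-treated patients cost the payer
$3.77M less and gain 48 QALYs relative to olanzapine — asenapine is
*dominant* (cheaper and more effective), driven by its lower drug price
and its lower weight-gain incidence (39.2% vs 55.1%), which feeds through
to fewer metabolic complications. `bipolarcua dsa` re-runs the model at
every parameter's lower and upper bound (tornado-ordered CSV), and
`bipolarcua psa --n-reps 10000 --seed 1` samples all parameters jointly:

```
moh: dominant in 96.8% of 2000 replications
societal: dominant in 96.8% of 2000 replications
```

The same library surface is available in Python via
`bipolarcua.run_model`, `bipolarcua.run_dsa`, `bipolarcua.run_psa`.

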