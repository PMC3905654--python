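# Configuration schema

A model configuration is one YAML file (see the packaged
`src/bipolarcua/data/base_case.yaml` for a complete example). Scalar
inputs accept either a plain number or a mapping
`{base: x, lower: l, upper: u}`; the bounds feed the sensitivity
analyses (either side may be `null` for "not published" — a ±25% band is
substituted). All currency is CAD-2011/year unless the key says
otherwise; probabilities are annual.

```yaml
arms:
  intervention:                 # and an identical `comparator` block
    name: <label>
    annual_drug_cost: <cost>
    p_weight_gain_y1: <probability>   # significant (>=7%) weight gain, year 1
    p_eps_y1: <probability>           # EPS-related event, year 1

switch:                         # shared by both arms
  p_switch_given_eps: <probability>
  annual_drug_cost: <cost>      # the drug switched to

risks:
  odds_ratio_weight_gain:       # per complication, per sex
    {diabetes|hypertension|chd|stroke}: {male: <ratio>, female: <ratio>}
  mortality:                    # mortality risk vs general population
    {diabetes|hypertension|chd|stroke}: {male: <ratio>, female: <ratio>}

utilities:
  u_bpd: <utility in [0,1]>
  du_weight_gain: <magnitude>   # permanent decrement
  du_eps: <magnitude>           # transient decrement
  eps_duration_years: 0.25      # fraction of year 1 under the EPS decrement
  wg_year1_exposure: 1.0        # fraction of year 1 under the wg decrement
  w_additional: <weight in [0,1]>   # non-worst concurrent disutilities
  du_complication:
    {complication}: {male: <magnitude>, female: <magnitude>}

costs:
  eps_management: <cost/event>
  direct:                       # complication medical costs
    diabetes: <cost>            # chronic, per year
    hypertension: <cost>
    chd_y1: <cost>              # event year
    chd_y2plus: <cost>          # subsequent years
    chd_fatal: <cost>           # one-time, on a fatal event
    stroke_y1: <cost>
    stroke_y2plus: <cost>
    stroke_fatal: <cost>
  productivity:                 # societal perspective, per year present
    {complication}: <cost>
  informal_care_stroke: <cost/year>

mortality:
  bpd_suicide_multiplier: <ratio>
  life_table:                   # one of three forms:
    gompertz: {male: {b: , c: }, female: {b: , c: }}  # q=1-exp(-b*e^{c*age})
    age_min: 18
    age_max: 80
    # table: [{sex: male, age: 40, value: 0.0018}, ...]
    # csv: path/to/file.csv     # columns: sex, age, value
  suicide:
    flat: {male: <q>, female: <q>}   # or table:/csv: as above
    age_min: 18
    age_max: 80

epidemiology:
  synthetic: {seed: <int>, scale: low|realistic|high, age_min: 18, age_max: 80}
  # or explicit:
  # prevalence: [{complication, sex, value}, ...]        (or {csv: path})
  # incidence:  [{complication, sex, age, value}, ...]   (or {csv: path};
  #              CSV columns: complication, sex, age, value)
  p_fatal_chd: <probability>
  p_fatal_stroke: <probability>

run:
  horizon_years: 5
  discount_rate: 0.05
  entry_age: 40
  sex_mix: 0.5                  # fraction male
  cohort_size_report: 1000
  seed: 0
  complication_order: [diabetes, hypertension, chd, stroke]
  or_as_rr: false               # apply weight-gain ORs as relative risks
  mortality_combination: multiplicative   # or "max"
  discount_first_year: false
  half_cycle_correction: false
```

`bipolarcua.save_parameters` writes a fully-resolved config (explicit
tables); loading it back reproduces the parameter object exactly.
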