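# Base-case parameterisation: asenapine vs olanzapine in bipolar disorder.
# Clinical and cost inputs carry the published base values with their
# lower/upper sensitivity bounds (null = not published; a +/-25% band is
# applied downstream).  Epidemiology and mortality tables are synthetic
# stand-ins generated in-package; fields marked "assumption" have no
# published value.
arms:
  intervention:
    name: asenapine
    annual_drug_cost: 1030.00          # no published interval; held fixed
    p_weight_gain_y1: {base: 0.392, lower: 0.294, upper: 0.490}
    p_eps_y1: {base: 0.107, lower: 0.072, upper: 0.149}
  comparator:
    name: olanzapine
    annual_drug_cost: {base: 1871.00, lower: 1316.00, upper: 2426.00}
    p_weight_gain_y1: {base: 0.551, lower: 0.413, upper: 0.689}
    p_eps_y1: {base: 0.095, lower: 0.068, upper: 0.131}

switch:
  # probability of switching (to aripiprazole) after an EPS event; taken over
  # from schizophrenia trials in the source analysis, value unpublished ->
  # assumption
  p_switch_given_eps: 0.20
  # aripiprazole annual cost, unpublished -> assumption (set to olanzapine's)
  annual_drug_cost: 1871.00

risks:
  odds_ratio_weight_gain:
    diabetes:
      male: {base: 2.69, lower: 2.17, upper: 3.34}
      female: {base: 1.9, lower: 1.5, upper: 2.3}
    hypertension:
      male: {base: 1.68, lower: 1.45, upper: 1.94}
      female: {base: 1.56, lower: 1.48, upper: 1.64}
    chd:
      male: {base: 1.68, lower: 1.13, upper: 2.5}
      female: {base: 1.25, lower: 1.01, upper: 1.55}
    stroke:
      male: {base: 1.02, lower: 1.01, upper: 1.03}
      female: {base: 1.02, lower: 1.01, upper: 1.03}
  mortality:
    diabetes:
      male: {base: 1.88, lower: 1.55, upper: 2.27}
      female: {base: 1.88, lower: 1.55, upper: 2.27}
    hypertension:
      male: {base: 1.44, lower: 1.00, upper: 2.88}
      female: {base: 1.34, lower: 1.00, upper: 2.68}
    chd:
      male: {base: 2.20, lower: 2.00, upper: 2.40}
      female: {base: 1.60, lower: 1.20, upper: 2.10}
    stroke:
      male: {base: 2.37, lower: 2.11, upper: 2.64}
      female: {base: 2.37, lower: 2.07, upper: 2.70}

utilities:
  u_bpd: {base: 0.800, lower: 0.580, upper: 1.000}
  du_weight_gain: {base: 0.066, lower: 0.050, upper: 0.083}
  du_eps: {base: 0.074, lower: 0.053, upper: 0.090}
  eps_duration_years: 0.25             # EPS disutility lasts three months
  wg_year1_exposure: 1.0               # fraction of year 1 under wg disutility
  # scenario weight on the non-worst concurrent complication disutilities
  # (0.5 / 1.0 are scenario values, not a confidence interval)
  w_additional: {base: 0.0, lower: 0.5, upper: 1.0}
  du_complication:                      # magnitudes subtracted from u_bpd
    diabetes:
      male: {base: 0.06, lower: 0.03, upper: 0.08}
      female: {base: 0.05, lower: 0.03, upper: 0.08}
    hypertension:
      male: {base: 0.02, lower: 0.00, upper: 0.03}
      female: {base: 0.00, lower: -0.01, upper: 0.02}
    chd:
      male: {base: 0.07, lower: 0.05, upper: 0.09}
      female: {base: 0.06, lower: 0.03, upper: 0.08}
    stroke:
      male: {base: 0.17, lower: 0.12, upper: 0.23}
      female: {base: 0.18, lower: 0.10, upper: 0.25}

costs:                                  # CAD 2011
  eps_management: {base: 60.00, lower: 0.00, upper: null}
  direct:
    diabetes: {base: 3834.77, lower: 1215.00, upper: 17072.00}
    hypertension: {base: 571.00, lower: 233.00, upper: 827.00}
    chd_fatal: {base: 7093.20, lower: 775.00, upper: 52617.00}
    chd_y1: {base: 2481.24, lower: 818.00, upper: 8819.00}
    chd_y2plus: {base: 1146.11, lower: 360.00, upper: 5795.00}
    stroke_fatal: {base: 30776.93, lower: 7362.00, upper: 34165.00}
    stroke_y1: {base: 4034.86, lower: 1395.00, upper: 10560.00}
    stroke_y2plus: {base: 1867.59, lower: 452.00, upper: 8692.00}
  productivity:
    diabetes: {base: 528.00, lower: 396.00, upper: 660.00}
    hypertension: {base: 119.00, lower: 89.25, upper: 148.75}
    chd: {base: 3109.00, lower: 2331.75, upper: 3886.25}
    stroke: {base: 4322.00, lower: 3241.50, upper: 5402.50}
  informal_care_stroke: {base: 3770.00, lower: 2827.50, upper: 4712.50}

mortality:
  bpd_suicide_multiplier: {base: 15.50, lower: 12.25, upper: 18.44}
  life_table:
    gompertz:
      male: {b: 5.0e-05, c: 0.09}
      female: {b: 3.0e-05, c: 0.09}
    age_min: 18
    age_max: 80
  suicide:
    flat: {male: 1.7e-04, female: 5.0e-05}
    age_min: 18
    age_max: 80

epidemiology:
  synthetic: {seed: 20110601, scale: realistic, age_min: 18, age_max: 80}
  p_fatal_chd: 0.10                    # assumption (claims-derived, unpublished)
  p_fatal_stroke: 0.15                 # assumption

run:
  horizon_years: 5
  discount_rate: 0.05
  entry_age: {base: 40, lower: 20, upper: null}
  sex_mix: 0.5                         # fraction male
  cohort_size_report: 1000
  seed: 0
  complication_order: [diabetes, hypertension, chd, stroke]
  or_as_rr: false
  mortality_combination: multiplicative
  discount_first_year: false
  half_cycle_correction: false
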