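# Default model configuration: effectiveness and cost inputs for the
# cost-effectiveness analysis of MS/MS newborn screening for glutaric
# aciduria type 1 (GA-I) under German health-system conditions, 2010 EUR.
#
# Each entry under `parameters:` is a DistributionSpec:
#   kind: point      -> {value}
#   kind: triangular -> {mode, min, max}   (optionally `base` to override the
#   kind: uniform    -> {min, max}          deterministic base-case value)
# Probabilities stated as "1 in N" may be written {one_in: N}.

cohort_size: 100000
discount_rate: 0.03
horizons: [20, 70]
gdp_per_capita: 38170        # 2010 per-capita GDP, international dollars

life_table:
  life_expectancy_at_birth: 79.45   # official German 2009 mortality table
  max_age: 110

# Marginal screening cost construction (recall-based): adding the C5DC
# marker to a pre-existing MS/MS panel costs only the extra recalls.
screening:
  recall_rate: 0.0008          # additional recall rate 0.08%
  cost_recall_exam: 31.01      # clinical re-examination + new blood sample
  cost_recall_test: 7.00       # repeated MS/MS analysis

# Confirmation testing after a positive screen: metabolite + mutation
# analysis always, enzyme activity only in unclear cases (~5%).
confirmation:
  cost_metabolite: 25.0
  cost_mutation: 800.0
  cost_enzyme: 800.0
  enzyme_fraction: 0.05

parameters:
  # --- epidemiology, prevalence and effectiveness -------------------------
  test_specificity:
    kind: point
    value: 1.0                 # perfect specificity incl. confirmation
  test_sensitivity:
    kind: triangular
    mode: 0.945
    min: 0.90
    max: 0.99
  prevalence:
    kind: triangular           # per-birth probability, sampled on the
    mode: {one_in: 112700}     # probability scale
    min: {one_in: 129455}
    max: {one_in: 95953}
  p_early_diagnosis:
    kind: triangular           # macrocephaly / high-risk screening route
    mode: 0.15
    min: 0.12
    max: 0.18
  p_smd_given_diagnosed:
    kind: triangular           # severe movement disorder despite treatment
    mode: 0.115
    min: 0.092
    max: 0.138
  p_smd_given_clinical:
    kind: triangular           # sMD after clinical (crisis) presentation
    mode: 0.74
    min: 0.592
    max: 0.888
  le_healthy:
    kind: point
    value: 79.45               # years; also the life-table target
  le_impaired:
    kind: uniform              # years; base case = midpoint 35
    min: 25.0
    max: 45.0
  disability_weight_smd:
    kind: uniform              # neurological sequelae weight; base case at
    min: 0.443                 # the published point value 0.471
    max: 0.471
    base: 0.471

  # --- cost assessment (2010 EUR) -----------------------------------------
  cost_crisis_diagnosis:
    kind: triangular           # diagnosis after acute encephalopathic crisis
    mode: 3000.0
    min: 2000.0
    max: 8000.0
  cost_confirmation:
    kind: point
    value: 865.0               # = 25 + 800 + 0.05 * 800
  cost_screen_per_neonate:
    kind: point
    value: 0.031
  cost_outpatient_visit:
    kind: triangular
    mode: 127.0
    min: 88.9
    max: 165.1
  cost_inpatient_stay:
    kind: triangular
    mode: 1335.0
    min: 934.5
    max: 1735.5
  cost_schooling_annual:
    kind: triangular           # special schooling, ages 6-16 inclusive
    mode: 5689.0
    min: 0.0
    max: 11369.0
  cost_special_care_annual:
    kind: triangular           # special care, after age 6
    mode: 2700.0
    min: 1890.0
    max: 3510.0
  cost_smd_overhead_annual:
    kind: uniform              # lump-sum overhead in the impaired state
    min: 0.0
    max: 3000.0

# PLACEHOLDER schedules. The source table marks annual visit counts and the
# annual dietary cost only as "age-depending" without printing numbers; the
# values below are guideline-informed stand-ins (intensive management with
# lysine-free amino-acid supplements through age 6, maintenance with
# carnitine thereafter) and are meant to be overridden with local data.
# All absolute cost results depend on these schedules.
schedules:
  outpatient_visits_by_age:    # visits / year
    - {age_min: 0, age_max: 6, annual_value: 4.0}
    - {age_min: 7, age_max: 110, annual_value: 2.0}
  inpatient_stays_by_age:      # admissions / year
    - {age_min: 0, age_max: 6, annual_value: 1.0}
    - {age_min: 7, age_max: 110, annual_value: 0.2}
  dietary_cost_by_age:         # EUR / year (diet + levocarnitine)
    - {age_min: 0, age_max: 6, annual_value: 3000.0}
    - {age_min: 7, age_max: 110, annual_value: 300.0}
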