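# Default scenario: breast-radiology department, 2019 accounting year.
# Three organizational strategies for the first-level screening waiting
# list: the current setup (32-month wait), one extra daytime team
# (22-month wait), and two extra afternoon teams (16-month wait).
#
# Currency values are strings so they parse to exact decimal euros.

tumor_model:
  doubling_time_days: 168.5          # calibrated: Td -> Tp sojourn ~ 4.6 years
  cell_density_per_cm3: 1.0e+9       # spherical tumor, standard packing
  detection_cells: 1.0e+7            # ~3 mm mammographic detection threshold
  palpability_cells: 1.0e+10         # ~27 mm self-detection threshold

costs:
  staff_annual: "856825.94"
  goods_services_annual: "225288.23"
  overheads_annual: "162317.13"
  equipment_annual: "54000.00"
  staff_daily_per_team: "608.28"     # average daily cost (5 h) per team
  goods_services_daily: "128.59"
  overheads_daily: "92.65"
  equipment_daily: "30.82"
  working_hours_per_day: 5
  working_days_3y: "728.37"          # back-solved 3-year projection horizon

tariffs:
  paying_exam_fee: "87.00"
  ticket_fee: "36.15"
  paying_fraction: "0.35"

strategies:
  - name: current
    waiting_months: 32
    teams_day: 2
    teams_afternoon: 0
    mammographs: 2
    ultrasounds: 3
    reporting_stations: 3
    exams_per_day: 40
    patients_3y: 30000
    overrides:                       # figures from the hospital accounts
      daily_cost: "1468.61"
      cost_3y: "1069687.68"
      unit_cost: "34.42"             # flagged: computed value is 36.72
  - name: 22-month
    waiting_months: 22
    teams_day: 3
    teams_afternoon: 0
    mammographs: 3
    ultrasounds: 4
    reporting_stations: 3
    exams_per_day: 60
    patients_3y: 45000
    overrides:
      daily_cost: "2715.99"
      cost_3y: "1978238.64"
  - name: 16-month
    waiting_months: 16
    teams_day: 2
    teams_afternoon: 2
    mammographs: 2
    ultrasounds: 3
    reporting_stations: 3
    exams_per_day: 80
    patients_3y: 60000
    overrides:
      daily_cost: "2906.40"
      daily_revenue: "7936.05"       # 80 x blended tariff would give 7972.20
      cost_3y: "2116927.08"

metastasis:
  reference_strategy: current
  n_effective: 242                   # registry size behind the Wilson CIs
  months_scale: 1.0
  observed_reference:                # per-stage metastasis probability under
    T1A: 0.00                        # the reference (32-month) waiting list
    T1B: 0.03
    T1C: 0.20
    T2: 0.59                         # T2 truncated at the palpability threshold

qol:
  non_met_first_year: 0.696
  non_met_subsequent: 0.779
  metastatic_all_years: 0.685

effects:
  reference_strategy: current
  survival_table: null               # null -> packaged synthetic SEER stand-in
  incident_patients:                 # [point, lo, hi] per strategy x stratum
    current:
      metastatic: [12.8, 12.5, 13.2]
      non_metastatic: [25.9, 25.7, 26.1]
    22-month:
      metastatic: [14.9, 14.7, 15.1]
      non_metastatic: [43.2, 43.1, 43.3]
    16-month:
      metastatic: [11.2, 11.1, 11.3]
      non_metastatic: [66.3, 66.2, 66.4]
  reported_qaly:                     # previously reported stratum QALYs,
    current:                         # used when use_printed_overrides is on
      metastatic: 10.3
      non_metastatic: 50.6
    22-month:
      metastatic: 12.0
      non_metastatic: 84.4
    16-month:
      metastatic: 9.0
      non_metastatic: 129.4

cohort:
  n: 242
  stage_counts: {T1A: 20, T1B: 65, T1C: 95, T2: 59, T3: 3}
  node_counts: {N0: 154, "N+": 88}
  histology_counts: {ductal: 189, lobular: 44, tubular: 5, mucinous: 2}
  grade_counts: {1: 79, 2: 109, 3: 47}   # 235 graded of 242; renormalized

report:
  use_printed_overrides: true
  willingness_to_pay: null           # EUR per QALY; null disables verdicts
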