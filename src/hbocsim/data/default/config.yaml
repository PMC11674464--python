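tables:
  hazards: hazards.csv
  lifetable: lifetable.csv
  parity_cdf: parity_cdf.csv
  maternal_age: maternal_age.csv
  predictive_uptake: predictive_uptake.csv
  screening_performance: screening_performance.csv
  screening_start: screening_start.csv
  surgery_uptake: surgery_uptake.csv
  survival: survival.csv
  gene_prevalence: gene_prevalence.csv
polygenic_hr_per_sd:
  breast: 1.6
  ovary: 1.32
polygenic_correlation: 0.0
referral_model:
  breast:
    constant: 3.23
    age_40_49: 0.38
    age_50_69: 0.22
    age_70_plus: 0.1
    survival_lt_12m: 0.35
    high_grade: 2.37
    non_triple_negative: 0.5
    her2: 0.22
  ovary:
    constant: 3.09
    age_60_74: 0.2
    age_75_plus: 0.08
    survival_lt_12m: 0.04
    high_grade: 1.06
    prior_breast: 17.75
    mucinous: 0.08
    other_histotype: 0.2
testing_uptake:
  breast: 0.96
  ovary: 0.95
male_predictive_rate_ratio: 0.422
paternal_age_shift: 2
max_children: 8
screening_config:
  population:
    age_stop: 74
    interval_target: 2
    interval_delay_p: 0.6
  high_risk:
    mammo_age_min: 25
    mammo_age_max: 64
    mri_age_min: 25
    mri_age_max: 59
    interval_target: 1
    interval_delay_p: 0.7
  moderate:
    mammo_age_min: 35
    mammo_age_max: 59
    start_shift: 10
surgery_config:
  risk_reduction:
    BRRM: 0.1
    RRSO: 0.05
  rrso_breast_multiplier: 1.0
  crrm_uptake:
    carrier: 0.45
    noncarrier: 0.05
survival_config:
  subtype_multiplier:
    TN: 1.8
    HER2: 1.1
    HR+: 0.85
  histology_multiplier:
    serous: 1.1
    clear_cell: 1.3
    endometrioid: 0.7
    mucinous: 0.9
    other: 1.2
  excess_years: 15
tumour_models:
  breast:
    subtype_by_gene:
      none:
        TN: 0.11
        HER2: 0.14
        HR+: 0.75
      BRCA1:
        TN: 0.65
        HER2: 0.05
        HR+: 0.3
      BRCA2:
        TN: 0.16
        HER2: 0.07
        HR+: 0.77
      PALB2:
        TN: 0.3
        HER2: 0.08
        HR+: 0.62
      CHEK2_1100delC:
        TN: 0.05
        HER2: 0.12
        HR+: 0.83
      ATM:
        TN: 0.06
        HER2: 0.1
        HR+: 0.84
      RAD51C:
        TN: 0.3
        HER2: 0.1
        HR+: 0.6
      RAD51D:
        TN: 0.3
        HER2: 0.1
        HR+: 0.6
      BRIP1:
        TN: 0.15
        HER2: 0.12
        HR+: 0.73
    grade_by_subtype:
      TN:
        1: 0.03
        2: 0.2
        3: 0.77
      HER2:
        1: 0.08
        2: 0.42
        3: 0.5
      HR+:
        1: 0.28
        2: 0.5
        3: 0.22
    size_by_mode:
      screen:
        <10: 0.34
        10-20: 0.45
        21-50: 0.18
        '>50': 0.03
      symptomatic:
        <10: 0.09
        10-20: 0.4
        21-50: 0.41
        '>50': 0.1
      baseline:
        <10: 0.09
        10-20: 0.4
        21-50: 0.41
        '>50': 0.1
    node_pos_by_size:
      <10: 0.08
      10-20: 0.2
      21-50: 0.42
      '>50': 0.65
    metastasis_by_nodes:
      negative: 0.01
      positive: 0.085
  ovary:
    histology_by_age:
      <50:
        serous: 0.35
        endometrioid: 0.25
        clear_cell: 0.15
        mucinous: 0.15
        other: 0.1
      50-69:
        serous: 0.52
        endometrioid: 0.17
        clear_cell: 0.1
        mucinous: 0.08
        other: 0.13
      70+:
        serous: 0.62
        endometrioid: 0.07
        clear_cell: 0.05
        mucinous: 0.05
        other: 0.21
    grade_by_histology:
      serous:
        1: 0.05
        2: 0.15
        3: 0.8
      endometrioid:
        1: 0.35
        2: 0.4
        3: 0.25
      clear_cell:
        1: 0.05
        2: 0.15
        3: 0.8
      mucinous:
        1: 0.5
        2: 0.3
        3: 0.2
      other:
        1: 0.2
        2: 0.3
        3: 0.5
    stage_by_grade:
      1:
        local: 0.5
        regional: 0.3
        distant: 0.2
      2:
        local: 0.3
        regional: 0.35
        distant: 0.35
      3:
        local: 0.15
        regional: 0.35
        distant: 0.5
    serous_distant_shift: 0.15
sojourn_dist:
  default:
    mu: 0.85
    sigma: 0.55
  BRCA1:
    mu: 0.5
    sigma: 0.5
  BRCA2:
    mu: 0.7
    sigma: 0.5
notes:
  family_history_counts_both_sides: true
  ovary_high_grade_min: 2
  breast_high_grade_min: 3
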