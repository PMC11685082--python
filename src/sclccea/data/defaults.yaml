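# Default model configuration: three first-line ES-SCLC strategies compared
# from the Chinese healthcare-system perspective.  Parameter entries are
# [base, low, high, distribution] in 2024 USD (converted at 7.13 RMB/USD).

clock:
  cycle_days: 21
  horizon_years: 10.0
  start_age_years: 62

discount:
  cost: 0.05
  qaly: 0.05

wtp_threshold: 37598.0
wtp_summary: [12533.0, 25065.0, 37598.0]

uplift_cutoff_years: 2.0
ec_n_cycles: 4
immunotherapy_cap_cycles: 35

strategies:
  benmel_anlo_ec:
    label: Benmelstobart+anlotinib+EC
    continuous_drugs: [benmelstobart, anlotinib]
    ae_events: [neutropenia, leukopenia, thrombocytopenia, anemia, hypertension]
  anlo_ec:
    label: Anlotinib+EC
    continuous_drugs: [anlotinib]
    ae_events: [neutropenia, leukopenia, thrombocytopenia, anemia,
                hypertriglyceridemia, hypertension]
  ec:
    label: EC
    continuous_drugs: []
    ae_events: [neutropenia, leukopenia, thrombocytopenia, anemia]

reference: ec

parameters:
  # treatment cost per 21-day cycle (USD)
  cost.benmelstobart:        [3444.60, 2583.45, 4305.75, gamma]
  cost.anlotinib:            [403.46, 272.08, 556.66, gamma]
  cost.etoposide:            [325.67, 228.69, 425.18, gamma]
  cost.carboplatin:          [65.87, 32.61, 123.90, gamma]
  cost.radiotherapy:         [26.33, 19.75, 32.91, gamma]
  cost.chemotherapy:         [77.36, 58.02, 96.70, gamma]
  cost.immunotherapy:        [5026.09, 3769.57, 6282.61, gamma]
  cost.best_supportive:      [332.85, 249.64, 416.07, gamma]
  cost.end_of_life:          [7985.90, 5989.42, 9982.37, gamma]
  # follow-up cost per visit (USD)
  cost.laboratory:           [399.54, 299.66, 499.43, gamma]
  cost.imaging:              [168.07, 126.05, 210.09, gamma]
  # adverse-event management cost per episode (USD)
  ae_cost.neutropenia:       [85.37, 64.02, 106.71, gamma]
  ae_cost.leukopenia:        [472.40, 354.30, 590.50, gamma]
  ae_cost.thrombocytopenia:  [1068.48, 801.36, 1335.60, gamma]
  ae_cost.anemia:            [515.18, 386.38, 643.97, gamma]
  ae_cost.hypertriglyceridemia: [122.29, 91.72, 152.86, gamma]
  ae_cost.hypertension:      [176.34, 132.26, 220.43, gamma]
  # health-state utilities
  utility.pfs:               [0.8400, 0.6300, 0.9000, beta]
  utility.pd:                [0.4730, 0.3548, 0.5913, beta]
  # adverse-event disutilities
  disutility.neutropenia:    [-0.0910, -0.1138, -0.0683, beta]
  disutility.leukopenia:     [-0.0910, -0.1138, -0.0683, beta]
  disutility.thrombocytopenia: [-0.1900, -0.2375, -0.1425, beta]
  disutility.anemia:         [-0.0730, -0.0913, -0.0548, beta]
  disutility.hypertriglyceridemia: [-0.0270, -0.0338, -0.0203, beta]
  disutility.hypertension:   [-0.0294, -0.1051, -0.0500, beta]
  # EQ-VAS utility uplift rate per arm (before the trial cutoff)
  uplift.benmel_anlo_ec:     [0.0471, 0.0353, 0.0588, beta]
  uplift.anlo_ec:            [0.0341, 0.0256, 0.0426, beta]
  uplift.ec:                 [0.0190, 0.0142, 0.0237, beta]
  # grade >=3 adverse-event incidences per arm
  ae_inc.benmel_anlo_ec.neutropenia:      [0.6950, 0.5213, 0.8688, beta]
  ae_inc.benmel_anlo_ec.leukopenia:       [0.3820, 0.2865, 0.4775, beta]
  ae_inc.benmel_anlo_ec.thrombocytopenia: [0.4960, 0.3720, 0.6200, beta]
  ae_inc.benmel_anlo_ec.anemia:           [0.2400, 0.1800, 0.3000, beta]
  ae_inc.benmel_anlo_ec.hypertension:     [0.1550, 0.1163, 0.1938, beta]
  ae_inc.anlo_ec.neutropenia:             [0.7300, 0.5475, 0.9125, beta]
  ae_inc.anlo_ec.leukopenia:              [0.3070, 0.2303, 0.3838, beta]
  ae_inc.anlo_ec.thrombocytopenia:        [0.5370, 0.4028, 0.6713, beta]
  ae_inc.anlo_ec.anemia:                  [0.2660, 0.1995, 0.3325, beta]
  ae_inc.anlo_ec.hypertriglyceridemia:    [0.0820, 0.0615, 0.1025, beta]
  ae_inc.anlo_ec.hypertension:            [0.1190, 0.0893, 0.1488, beta]
  ae_inc.ec.neutropenia:                  [0.6870, 0.5153, 0.8588, beta]
  ae_inc.ec.leukopenia:                   [0.3460, 0.2595, 0.4325, beta]
  ae_inc.ec.thrombocytopenia:             [0.3580, 0.2685, 0.4475, beta]
  ae_inc.ec.anemia:                       [0.2360, 0.1770, 0.2950, beta]
  # subsequent-treatment category proportions per arm
  mix.benmel_anlo_ec.radiotherapy:        [0.0690, 0.0517, 0.0862, beta]
  mix.benmel_anlo_ec.chemotherapy:        [0.2091, 0.1568, 0.2614, beta]
  mix.benmel_anlo_ec.targeted:            [0.0798, 0.0598, 0.0997, beta]
  mix.benmel_anlo_ec.immunotherapy:       [0.0690, 0.0517, 0.0862, beta]
  mix.benmel_anlo_ec.best_supportive:     [0.5732, 0.4299, 0.7165, beta]
  mix.anlo_ec.radiotherapy:               [0.0980, 0.0735, 0.1225, beta]
  mix.anlo_ec.chemotherapy:               [0.2919, 0.2189, 0.3648, beta]
  mix.anlo_ec.targeted:                   [0.1084, 0.0813, 0.1355, beta]
  mix.anlo_ec.immunotherapy:              [0.0855, 0.0641, 0.1068, beta]
  mix.anlo_ec.best_supportive:            [0.4163, 0.3122, 0.5204, beta]
  mix.ec.radiotherapy:                    [0.1131, 0.0849, 0.1414, beta]
  mix.ec.chemotherapy:                    [0.3494, 0.2620, 0.4367, beta]
  mix.ec.targeted:                        [0.1449, 0.1087, 0.1811, beta]
  mix.ec.immunotherapy:                   [0.1052, 0.0789, 0.1315, beta]
  mix.ec.best_supportive:                 [0.2874, 0.2156, 0.3593, beta]

psa:
  n_draws: 10000
  seed: 20240001
  uplift_correlation: 0.9
  chemo_bsc_correlation: -0.9

survival:
  # default model suite for the automated AIC ranking; the full 14-family
  # suite is available through the library API
  families: [exponential, weibull, gompertz, lognormal, loglogistic, gamma,
             rp_hazard, rp_odds, rp_normal]

synthetic_trial:
  # ETER701-like study conditions (medians in months)
  os_median_months: {benmel_anlo_ec: 19.3, anlo_ec: 13.3, ec: 11.9}
  pfs_median_months: {benmel_anlo_ec: 6.9, anlo_ec: 5.6, ec: 4.2}
  n_patients: {benmel_anlo_ec: 246, anlo_ec: 245, ec: 247}
  max_followup_months: 30.0
  censor_rate_per_day: 0.0004
  digitize_grid_step_days: 7.0
  risk_table_interval_months: 3.0
  digitize_noise: 0.0

scenarios:
  - name: benmelstobart_price_60pct
    price_multipliers: {benmelstobart: 0.6}
  - name: os_from_hr_0.86
    os_from_hr: {strategy: anlo_ec, reference: ec, hr: 0.86}
  - name: os_from_hr_0.67
    os_from_hr: {strategy: anlo_ec, reference: ec, hr: 0.67}
  - name: os_from_hr_1.10
    os_from_hr: {strategy: anlo_ec, reference: ec, hr: 1.10}
  - name: discount_utilities_only
    discount_mode: utilities_only
  - name: discount_costs_only
    discount_mode: costs_only
  - name: no_discounting
    discount_mode: none
  - name: horizon_5y
    horizon_years: 5.0
  - name: horizon_2y
    horizon_years: 2.0
  - name: no_best_supportive_care
    drop_best_supportive: true
  - name: no_end_of_life_care
    drop_end_of_life: true
  - name: utilities_not_adjusted
    uplift_rates_zeroed: true
  - name: ae_repeat_at_pd_entry
    ae_repeat_at_pd_entry: true
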