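# Default analysis configuration: three-strategy adjuvant model for
# resected stage II-IIIB gastric cancer, Chinese healthcare perspective,
# 2010 USD.  Parameter rows mirror the published input table names for
# auditability.

settings:
  cycle_length_weeks: 6
  weeks_per_year: 52
  horizon_years: 30
  annual_discount_rate: 0.03
  half_cycle_correction: false

wtp_threshold: 13527        # 3x 2010 Chinese per-capita GDP, USD/QALY
bsa_m2: 1.72                # body surface area used for dose rounding

survival:
  # Weibull survivor parameters of the pooled surgery-only reference,
  # time in 6-week cycles; active arms are scale x hazard-ratio.
  reference:
    pfs: {scale: 0.017869, shape: 1.055532}
    os: {scale: 0.005483, shape: 1.19}
  hazard_ratios:
    XELOX: {pfs: 0.56, os: 0.72}
    S-1: {pfs: 0.62, os: 0.68}

psa:
  n_replicates: 1000
  seed: 12345
  wtp_grid: {start: 0, stop: 100000, step: 2000}

# Uncertain inputs: median, range and distribution family.  `target` is the
# model parameter each row drives.
parameters:
  - {name: "Capecitabine per 500mg", target: cost_capecitabine,
     median: 6.3, low: 5.04, high: 6.3, distribution: lognormal}
  - {name: "Oxaliplatin per 50mg", target: cost_oxaliplatin,
     median: 232.8, low: 50.4, high: 688.7, distribution: lognormal}
  - {name: "Paclitaxel per 30mg", target: cost_paclitaxel,
     median: 115.4, low: 67.9, high: 234.9, distribution: lognormal}
  - {name: "S-1 per 20mg", target: cost_s1,
     median: 8.6, low: 4.3, high: 12.9, distribution: lognormal}
  - {name: "Laboratory evaluations per episode", target: cost_lab_eval,
     median: 87.6, low: 35.2, high: 182.7, distribution: lognormal}
  - {name: "Administration per episode", target: cost_administration,
     median: 18.5, low: 15.0, high: 23.0, distribution: lognormal}
  - {name: "Supportive care per 3 weeks", target: cost_supportive_care,
     median: 1415.4, low: 1022.8, high: 2021.5, distribution: lognormal}
  - {name: "Abdominal CT per episode", target: cost_abdominal_ct,
     median: 105.2, low: 52.6, high: 157.8, distribution: gamma}
  - {name: "Abdominal MRI per episode", target: cost_abdominal_mri,
     median: 140.8, low: 70.4, high: 211.2, distribution: gamma}
  - {name: "Chest radiograph per episode", target: cost_chest_radiograph,
     median: 8.4, low: 4.2, high: 12.6, distribution: gamma}
  - {name: "Nausea and vomiting per episode", target: cost_ae_nausea_vomiting,
     median: 39.6, low: 17.9, high: 76.5, distribution: lognormal}
  - {name: "Neutropenia per episode", target: cost_ae_neutropenia,
     median: 530.8, low: 198.5, high: 863.1, distribution: lognormal}
  - {name: "Decreased appetite, Anorexia, Fatigue and Asthenia per episode",
     target: cost_ae_appetite_fatigue,
     median: 115.4, low: 103.8, high: 126.9, distribution: lognormal}
  - {name: "Diarrhoea and abdominal pain per episode",
     target: cost_ae_diarrhoea_pain,
     median: 44.3, low: 28.5, high: 54.6, distribution: lognormal}
  - {name: "Thrombocytopenia per episode", target: cost_ae_thrombocytopenia,
     median: 3551.7, low: 3156.8, high: 3980.2, distribution: lognormal}
  - {name: "Risk of nausea and vomiting (XELOX)",
     target: risk_xelox_nausea_vomiting,
     median: 0.15, low: 0.12, high: 0.18, distribution: beta}
  - {name: "Risk of neutropenia (XELOX)", target: risk_xelox_neutropenia,
     median: 0.22, low: 0.176, high: 0.264, distribution: beta}
  - {name: "Risk of decreased appetite, fatigue and asthenia (XELOX)",
     target: risk_xelox_appetite_fatigue,
     median: 0.12, low: 0.096, high: 0.144, distribution: beta}
  - {name: "Risk of diarrhoea and abdominal pain (XELOX)",
     target: risk_xelox_diarrhoea_pain,
     median: 0.04, low: 0.032, high: 0.048, distribution: beta}
  - {name: "Risk of thrombocytopenia (XELOX)",
     target: risk_xelox_thrombocytopenia,
     median: 0.08, low: 0.064, high: 0.096, distribution: beta}
  - {name: "Risk of nausea (S-1)", target: risk_s1_nausea,
     median: 0.037, low: 0.0296, high: 0.0444, distribution: beta}
  - {name: "Risk of diarrhoea (S-1)", target: risk_s1_diarrhoea,
     median: 0.031, low: 0.0248, high: 0.0372, distribution: beta}
  - {name: "Risk of anorexia (S-1)", target: risk_s1_anorexia,
     median: 0.06, low: 0.048, high: 0.072, distribution: beta}
  - {name: "Risk for requiring second-line chemotherapy",
     target: risk_second_line,
     median: 0.25, low: 0.2, high: 0.3, distribution: beta}
  - {name: "Utility of DFS years 1-5 (XELOX)", target: utility_dfs_xelox_y0_5,
     median: 0.68, low: 0.56, high: 0.76, distribution: beta}
  - {name: "Utility of DFS years 5-10 (XELOX)", target: utility_dfs_xelox_y5_10,
     median: 0.81, low: 0.648, high: 0.972, distribution: beta}
  - {name: "Utility of DFS years 1-10 (S-1)", target: utility_dfs_s1,
     median: 0.81, low: 0.648, high: 0.972, distribution: beta}
  - {name: "Utility of DFS years 1-10 (SO)", target: utility_dfs_so,
     median: 0.81, low: 0.648, high: 0.972, distribution: beta}
  - {name: "Utility of PS (all arms)", target: utility_ps,
     median: 0.5, low: 0.4, high: 0.6, distribution: beta}

# One-way analysis additionally varies the discount rate over the
# guideline range; it is not sampled in the PSA.
one_way_extra:
  - {name: "Annual discount rate", target: discount_rate,
     median: 0.03, low: 0.0, high: 0.08, distribution: fixed}
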