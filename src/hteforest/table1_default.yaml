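# Default synthetic-trial configuration calibrated to the published
# baseline characteristics of the two glycemic-control trials.
# Cell sizes, per-cell means/SDs and proportions follow the published
# per-study, per-arm table; the within-study glucose-HbA1c correlation of
# 0.52 makes the downstream hemoglobin glycation index reproduce the
# published between-study contrast (ACCORD ~0, VADT ~0.8).
seed: 0
rho_glucose_hba1c: 0.52
followup_years:
  ACCORD: 3.7
  VADT: 5.6
dropout_rate: 0.0
truncation:
  age: [40, 85]
  bmi: [17, 60]
  glucose: [60, 500]
  creatinine: [0.3, 3.0]
base_risk:
  intercept: 0.09
  terms:
    - {var: age, coef: 0.002, center: 62.4}
    - {var: history_mi, coef: 0.03}
    - {var: current_smoker, coef: 0.01}
mortality_base_risk:
  intercept: 0.07
  terms:
    - {var: age, coef: 0.0015, center: 62.4}
default_tau: 0.0
# Rule-based true treatment-effect heterogeneity: eight mutually exclusive
# cells on five modifiers (hgi, egfr, glucose, age, bmi), taus in the range
# of the published subgroup risk differences (including -5.1% and +3.1%).
effect_rules:
  - conditions:
      - {var: hgi, op: ge, value: 0.84}
    tau: 0.031
  - conditions:
      - {var: hgi, op: lt, value: 0.84}
      - {var: egfr, op: lt, value: 69}
      - {var: age, op: ge, value: 61}
    tau: 0.050
  - conditions:
      - {var: hgi, op: lt, value: 0.84}
      - {var: egfr, op: lt, value: 69}
      - {var: age, op: lt, value: 61}
    tau: -0.020
  - conditions:
      - {var: hgi, op: lt, value: 0.84}
      - {var: egfr, op: ge, value: 69}
      - {var: glucose, op: ge, value: 228}
    tau: -0.045
  - conditions:
      - {var: hgi, op: lt, value: -0.3}
      - {var: egfr, op: ge, value: 69}
      - {var: glucose, op: lt, value: 228}
      - {var: bmi, op: ge, value: 30}
    tau: -0.051
  - conditions:
      - {var: hgi, op: lt, value: -0.3}
      - {var: egfr, op: ge, value: 69}
      - {var: glucose, op: lt, value: 228}
      - {var: bmi, op: lt, value: 30}
    tau: 0.010
  - conditions:
      - {var: hgi, op: ge, value: -0.3}
      - {var: hgi, op: lt, value: 0.84}
      - {var: egfr, op: ge, value: 69}
      - {var: glucose, op: lt, value: 228}
      - {var: age, op: lt, value: 61}
    tau: -0.042
  - conditions:
      - {var: hgi, op: ge, value: -0.3}
      - {var: hgi, op: lt, value: 0.84}
      - {var: egfr, op: ge, value: 69}
      - {var: glucose, op: lt, value: 228}
      - {var: age, op: ge, value: 61}
    tau: 0.0
mortality_default_tau: 0.0
mortality_rules:
  - conditions:
      - {var: hgi, op: ge, value: 0.84}
    tau: 0.015
cells:
  ACCORD:
    0:
      n: 5123
      continuous:
        age: [62.8, 6.7]
        hba1c: [8.3, 1.1]
        glucose: [175.7, 56.4]
        total_cholesterol: [183.3, 41.6]
        triglycerides: [189.4, 148.6]
        ldl: [104.9, 33.8]
        hdl: [41.9, 11.5]
        creatinine: [0.9, 0.2]
        alt: [27.7, 14.9]
        sbp: [136.5, 17.2]
        dbp: [75.0, 10.7]
        bmi: [32.2, 5.4]
        diabetes_duration: [10.9, 7.6]
      binary:
        female: 0.384
        black: 0.187
        hispanic: 0.074
        insulin_use: 0.358
        sulfonylurea_use: 0.529
        metformin_use: 0.641
        glinide_use: 0.026
        acarbose_use: 0.009
        thiazolidinedione_use: 0.220
        history_amputation: 0.021
        history_eye_surgery: 0.229
        current_smoker: 0.118
        history_mi: 0.157
        history_stroke: 0.063
        history_chf: 0.048
        history_angina: 0.109
        prior_revascularization: 0.109
    1:
      n: 5128
      continuous:
        age: [62.8, 6.6]
        hba1c: [8.3, 1.1]
        glucose: [174.7, 55.9]
        total_cholesterol: [183.3, 42.1]
        triglycerides: [190.9, 148.2]
        ldl: [104.9, 34.0]
        hdl: [41.8, 11.8]
        creatinine: [0.9, 0.2]
        alt: [27.5, 17.4]
        sbp: [136.2, 17.0]
        dbp: [74.8, 10.7]
        bmi: [32.2, 5.4]
        diabetes_duration: [10.7, 7.6]
      binary:
        female: 0.387
        black: 0.194
        hispanic: 0.070
        insulin_use: 0.341
        sulfonylurea_use: 0.540
        metformin_use: 0.637
        glinide_use: 0.025
        acarbose_use: 0.010
        thiazolidinedione_use: 0.221
        history_amputation: 0.022
        history_eye_surgery: 0.219
        current_smoker: 0.125
        history_mi: 0.153
        history_stroke: 0.059
        history_chf: 0.049
        history_angina: 0.119
        prior_revascularization: 0.120
  VADT:
    0:
      n: 899
      continuous:
        age: [60.3, 8.6]
        hba1c: [9.4, 1.6]
        glucose: [205.9, 69.0]
        total_cholesterol: [184.7, 52.7]
        triglycerides: [222.8, 351.8]
        ldl: [108.2, 34.0]
        hdl: [35.8, 10.4]
        creatinine: [1.0, 0.2]
        alt: [31.9, 17.4]
        sbp: [131.8, 16.8]
        dbp: [76.1, 10.2]
        bmi: [31.2, 4.4]
        diabetes_duration: [11.5, 7.2]
      binary:
        female: 0.029
        black: 0.164
        hispanic: 0.151
        insulin_use: 0.519
        sulfonylurea_use: 0.624
        metformin_use: 0.703
        glinide_use: 0.004
        acarbose_use: 0.018
        thiazolidinedione_use: 0.190
        history_amputation: 0.030
        history_eye_surgery: 0.183
        current_smoker: 0.162
        history_mi: 0.190
        history_stroke: 0.046
        history_chf: 0.053
        history_angina: 0.185
        prior_revascularization: 0.204
    1:
      n: 892
      continuous:
        age: [60.5, 8.8]
        hba1c: [9.4, 1.5]
        glucose: [203.5, 67.8]
        total_cholesterol: [181.6, 40.4]
        triglycerides: [200.8, 161.8]
        ldl: [107.0, 30.9]
        hdl: [36.2, 9.9]
        creatinine: [1.0, 0.2]
        alt: [30.8, 15.2]
        sbp: [131.4, 16.6]
        dbp: [76.0, 10.4]
        bmi: [31.3, 4.4]
        diabetes_duration: [11.5, 7.8]
      binary:
        female: 0.029
        black: 0.170
        hispanic: 0.174
        insulin_use: 0.522
        sulfonylurea_use: 0.593
        metformin_use: 0.678
        glinide_use: 0.006
        acarbose_use: 0.022
        thiazolidinedione_use: 0.186
        history_amputation: 0.031
        history_eye_surgery: 0.189
        current_smoker: 0.173
        history_mi: 0.186
        history_stroke: 0.063
        history_chf: 0.068
        history_angina: 0.187
        prior_revascularization: 0.204
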