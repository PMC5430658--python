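# Default two-group cohort presets: per-cell parameter distributions
# (mean, SD) patterned on the reported healthy / diabetic group statistics,
# and plausible per-subject HbA1c levels (the study reports only their
# ordering, so representative clinical values are used).
groups:
  healthy:
    volume_fl: {mean: 90.5, sd: 11.4}
    hb_g_dl: {mean: 33.4, sd: 2.8}
    sigma_nm: {mean: 55.1, sd: 6.9}
    hba1c_pct: [4.8, 5.0, 5.2, 5.4, 5.5, 5.6]
  diabetic:
    volume_fl: {mean: 90.2, sd: 10.9}
    hb_g_dl: {mean: 34.6, sd: 2.7}
    sigma_nm: {mean: 46.6, sd: 4.5}
    hba1c_pct: [6.8, 7.3, 7.9, 8.6, 9.4, 10.2]
n_subjects: 6
n_cells: 40
between_subject_fraction: 0.6
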