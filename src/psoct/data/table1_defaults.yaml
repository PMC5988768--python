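# Default grade presets: group retardation-gradient statistics (rad/mm) of the
# bovine indentation study, per imaging configuration.  true_brc_mean and
# true_brc_sd are the between-sample mean and SD; n_samples the group size.
presets:
  - {grade_label: G0, config_label: XZ_indented,    true_brc_mean: 3.0, true_brc_sd: 0.5, n_samples: 10, banding_asymmetry: 0.15}
  - {grade_label: G1, config_label: XZ_indented,    true_brc_mean: 1.7, true_brc_sd: 0.4, n_samples: 8,  banding_asymmetry: 0.15}
  - {grade_label: G2, config_label: XZ_indented,    true_brc_mean: 1.8, true_brc_sd: 0.7, n_samples: 8,  banding_asymmetry: 0.15}
  - {grade_label: G0, config_label: XZ_nonindented, true_brc_mean: 1.1, true_brc_sd: 0.5, n_samples: 10, banding_asymmetry: 0.0}
  - {grade_label: G1, config_label: XZ_nonindented, true_brc_mean: 1.2, true_brc_sd: 0.3, n_samples: 8,  banding_asymmetry: 0.0}
  - {grade_label: G2, config_label: XZ_nonindented, true_brc_mean: 1.3, true_brc_sd: 0.5, n_samples: 8,  banding_asymmetry: 0.0}
  - {grade_label: G0, config_label: XY,             true_brc_mean: 5.2, true_brc_sd: 1.0, n_samples: 10, banding_asymmetry: 0.0}
  - {grade_label: G1, config_label: XY,             true_brc_mean: 4.9, true_brc_sd: 1.0, n_samples: 8,  banding_asymmetry: 0.0}
  - {grade_label: G2, config_label: XY,             true_brc_mean: 5.4, true_brc_sd: 1.5, n_samples: 8,  banding_asymmetry: 0.0}
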