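# Default synthetic agreement study: a 300-case cohort with log-normal ICH
# volumes (median 26.0 mL, IQR 9.3-59.2), 50% IVH prevalence, 66%
# basal-ganglia/thalamus location, measured by the voxel reference, ABC/2
# readers and the calibrated automated-segmentation error model.
cohort:
  n_cases: 300
  volume_median_mL: 26.0
  volume_iqr_mL: [9.3, 59.2]
  ivh_prevalence: 0.5
  basal_ganglia_fraction: 0.66
  irregularity_range: [0.1, 0.8]
  slice_thickness_mm: 1
  seed: 0
error_model:
  detect_intercept: -2.9803
  detect_slope: 1.8221
  p_ivh_include: 0.885135135135135
  p_partial: 0.22
  partial_fraction_range: [0.2, 0.6]
  p_distractor_include: 0.4
  distractor_volume_mL_range: [0.5, 3.0]
  multiplicative_noise_sd: 0.25
reader_sd: 0.10
repeat_fraction: 0.10
acceptance_limit_pct: 10.0
tau_threshold: 0.1
seed: 0
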