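# Calibrated group presets for the synthetic cane-gait generator.
#
# base_params holds the robust (non-frail) walking profile; each profile
# overrides fields per group. The default frail preset encodes the
# observed group pattern: smaller VT/AP oscillation amplitude, smaller
# AP swing angular velocity, and VT harmonic weight shifted toward
# higher harmonics (raising VT mean power frequency). Amplitude deltas
# are calibrated so that a default-composition cohort (14/31 subjects,
# 37/94 trials) yields a VT-RMS rank effect size near r = 0.36.

base_params:
  stride_time_mean_s: 1.10
  stride_time_sd_s: 0.05
  a_vt: 2.2
  a_ap: 1.8
  a_ml: 1.0
  weights_vt: [0.55, 0.25, 0.12, 0.08]
  weights_ap: [0.60, 0.22, 0.11, 0.07]
  weights_ml: [0.65, 0.20, 0.10, 0.05]
  impact_amp: 12.0
  impact_tau_s: 0.05
  g_vt: 30.0
  g_ap: 100.0
  g_ml: 40.0
  noise_acc: 0.15
  noise_gyro: 1.5
  n_strides: 8
  sample_rate_hz: 120.0
  lead_in_s: 0.6
  tail_s: 0.5
  include_gravity: true

profiles:
  default:
    robust: {}
    frail:
      a_vt: 2.015
      a_ap: 1.680
      impact_amp: 11.0
      g_ap: 93.0
      weights_vt: [0.50, 0.26, 0.15, 0.09]
    kcl_p_negative: {robust: 0.15, frail: 0.85}
    subject_amp_sd: 0.1
    subject_gyro_sd: 0.1
    subject_stride_sd: 0.03
    trial_amp_sd: 0.05

  # identical groups: the null cohort for classifier calibration checks
  zero_signal:
    robust: {}
    frail: {}
    kcl_p_negative: {robust: 0.15, frail: 0.85}

  # exaggerated group separation for classifier sanity checks
  well_separated:
    robust: {}
    frail:
      a_vt: 1.1
      a_ap: 0.9
      a_ml: 0.6
      impact_amp: 6.0
      g_vt: 18.0
      g_ap: 55.0
      g_ml: 24.0
      weights_vt: [0.40, 0.27, 0.20, 0.13]
      stride_time_mean_s: 1.35
    kcl_p_negative: {robust: 0.15, frail: 0.85}
    subject_amp_sd: 0.05
    subject_gyro_sd: 0.05
    subject_stride_sd: 0.02
    trial_amp_sd: 0.03
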