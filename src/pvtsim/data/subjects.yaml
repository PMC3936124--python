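# Synthetic-subject presets.
# "satiated": sleep-satiated baseline calibrated to the 240-ms mean / 29-ms SD
#   rested-RT anchor; lapse probability zero at zero deficit (lapses emerge
#   with sleep pressure), occasional false starts.
# "tsd85h": the same physiology with lapse coupling and false starts enabled,
#   intended for total-sleep-deprivation studies (e.g. 85 h awake, sessions
#   every 2 h).
satiated:
  baseline_mu_ms: 240.0
  baseline_sigma_ms: 29.0
  s_tau_wake_h: 16.0
  s_gain_ms: 120.0
  c_amplitude_ms: 40.0
  c_phase_h: 5.0
  lapse_base_p: 0.0
  lapse_gain: 0.0
  false_start_rate_per_s: 0.005
tsd85h:
  baseline_mu_ms: 240.0
  baseline_sigma_ms: 29.0
  s_tau_wake_h: 16.0
  s_gain_ms: 120.0
  c_amplitude_ms: 40.0
  c_phase_h: 5.0
  lapse_base_p: 0.01
  lapse_gain: 2.0
  false_start_rate_per_s: 0.01
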