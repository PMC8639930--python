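# Detector-fidelity scenario: wild-type baseline noise structure with all
# five arrhythmia classes injected at 50 events per 24 h each, so per-class
# precision/recall estimates have adequate support.  A testing scenario, not
# a biological calibration.
mu_rr_day_ms: 136.81
mu_rr_night_ms: 112.27
sigma_white_ms: 4.62448
sigma_white_night_ms: 3.37289
ar_phi: 0.998
sigma_slow_ms: 1.65331
sigma_slow_night_ms: 1.46823
pr_mean_ms: 35.0
pr_sd_ms: 1.5
qt_mean_ms: 28.0
qt_sd_ms: 1.5
event_rates_per_24h:
  escape_short: 50.0
  escape_long: 50.0
  av_block: 50.0
  premature: 50.0
  tachy_brady: 50.0
drug_schedule: []
duration_h: 24.0
lights_on_clock: "07:00"
t0_clock: "07:00"
genotype: wt
animal_id: mixed_sim
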