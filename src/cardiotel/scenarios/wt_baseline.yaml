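# Wild-type 24-h baseline telemetry.
# Phase-mean RR and noise calibrated to the wild-type night/day HRV rows:
#   NN night/day 112.27/136.81 ms, SDNN 23.47/26.56 ms, RMSSD 4.77/6.54 ms.
# sigma_white = RMSSD/sqrt(2); AR(1) innovation SD chosen so the stationary
# drift + white variance reproduces SDNN at ar_phi = 0.998.
# Arrhythmia rates: average wild-type counts per 24 h (short escapes 53,
# long escapes 1, AV blocks 0.6); premature/tachy-brady rates are nominal
# small values (not printed for wild type).
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
  escape_short: 53.0
  escape_long: 1.0
  av_block: 0.6
  premature: 1.0
  tachy_brady: 0.5
drug_schedule: []
duration_h: 24.0
lights_on_clock: "07:00"
t0_clock: "07:00"
genotype: wt
animal_id: wt_sim
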