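# Knockout 24-h baseline telemetry.
# Calibrated to the knockout night/day HRV rows:
#   NN night/day 110.00/111.63 ms, SDNN 24.05/23.17 ms, RMSSD 5.05/4.69 ms.
# Arrhythmia rates: average knockout counts per 24 h (short escapes 204,
# long escapes 117, AV blocks 30); premature/tachy-brady described only as
# "few", encoded as 5 per 24 h each.
mu_rr_day_ms: 111.63
mu_rr_night_ms: 110.0
sigma_white_ms: 3.31633
sigma_white_night_ms: 3.57089
ar_phi: 0.998
sigma_slow_ms: 1.44958
sigma_slow_night_ms: 1.50344
pr_mean_ms: 35.0
pr_sd_ms: 1.5
qt_mean_ms: 28.0
qt_sd_ms: 1.5
event_rates_per_24h:
  escape_short: 204.0
  escape_long: 117.0
  av_block: 30.0
  premature: 5.0
  tachy_brady: 5.0
drug_schedule: []
duration_h: 24.0
lights_on_clock: "07:00"
t0_clock: "07:00"
genotype: ko
animal_id: ko_sim
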