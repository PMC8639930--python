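# Knockout atropine challenge (peak HR 758 beats/min).
mu_rr_day_ms: 111.63
mu_rr_night_ms: 110.0
sigma_white_ms: 3.31633
ar_phi: 0.998
sigma_slow_ms: 0.37928
pr_mean_ms: 35.0
pr_sd_ms: 1.5
qt_mean_ms: 28.0
qt_sd_ms: 1.5
event_rates_per_24h: {}
drug_schedule:
  - drug: atropine
    t_injection_s: 1800.0
    target_hr_bpm: 758.0
    tau_onset_s: 120.0
    plateau_s: 2400.0
    tau_recovery_s: 900.0
duration_h: 2.5
lights_on_clock: "07:00"
t0_clock: "09:00"
genotype: ko
animal_id: ko_atr
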