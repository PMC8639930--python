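# Wild-type carbachol challenge (plateau HR 448 beats/min).
mu_rr_day_ms: 136.81
mu_rr_night_ms: 112.27
sigma_white_ms: 4.62448
ar_phi: 0.998
sigma_slow_ms: 0.37928
pr_mean_ms: 35.0
pr_sd_ms: 1.5
qt_mean_ms: 28.0
qt_sd_ms: 1.5
event_rates_per_24h: {}
drug_schedule:
  - drug: carbachol
    t_injection_s: 1800.0
    target_hr_bpm: 448.0
    tau_onset_s: 60.0
    plateau_s: 1200.0
    tau_recovery_s: 600.0
duration_h: 2.5
lights_on_clock: "07:00"
t0_clock: "09:00"
genotype: wt
animal_id: wt_cch
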