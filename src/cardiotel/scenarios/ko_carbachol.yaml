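# Knockout carbachol challenge: 30 min baseline + 2 h post injection,
# daytime session.  Plateau HR set to the knockout carbachol nadir
# (335 beats/min); ~1 h total effect (fast onset, 20 min hold, 10-min
# recovery constant).  Slow-drift amplitude reduced (stationary ~6 ms)
# relative to the 24-h baseline scenarios: a short post-handling
# pharmacological clamp suppresses the circadian/behavioural variability
# that the baseline SDNN calibration encodes.
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
  - drug: carbachol
    t_injection_s: 1800.0
    target_hr_bpm: 335.0
    tau_onset_s: 60.0
    plateau_s: 1200.0
    tau_recovery_s: 600.0
duration_h: 2.5
lights_on_clock: "07:00"
t0_clock: "09:00"
genotype: ko
animal_id: ko_cch
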