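# Methods

This note documents the models, calibrations, numerical choices and known
limitations behind `cardiotel`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

A recording is a time-ordered stream of beat annotations (P waves and R
peaks) with a P-wave morphology tag (`sinus`/`ectopic`) and optional
per-beat PR/QT on R rows.  The event-stream representation (rather than one
row per beat) is deliberate: AV block — a P wave without a following QRS —
is representable.  Times are seconds from recording start (float); all
intervals are reported in ms; all analysis windows are half-open
`[start, end)` so tilings are unambiguous.  When a P and an R share a
timestamp the P is ordered first (physiological order).  Day/night phase
windows derive from the `lights_on_clock` / `t0_clock` metadata under the
standard 12 h light : 12 h dark cycle; activity channels are not used.
Multi-day recordings are collapsed to the first complete 24 h.

## Synthetic telemetry generator

### RR process

Per beat,

    RR_i = mu(phase(t_i)) / f(t_i) + d_i + w_i

with `mu` the phase-mean RR (day/night), `f` the multiplicative drug HR
factor (divides RR so %-of-baseline analyses are scale-free), `w` i.i.d.
Gaussian white noise (SD `sigma_white`, per phase) and `d` an AR(1) drift
`d_i = phi·d_{i-1} + eps_i` with innovation SD `sigma_slow`.  Additive
AR(1) + white is the simplest process whose SDNN and RMSSD are
independently tunable:

    SDNN^2  ≈ sigma_white^2 + sigma_slow^2/(1 - phi^2)
    RMSSD^2 ≈ 2·sigma_white^2 + 2·sigma_slow^2·(1-phi)/(1-phi^2)

Since beat times depend on the intervals themselves, the self-consistent
solution is found by a 4-step fixed-point iteration on the beat-time grid
(the modulating signals vary on ≥ 60 s scales; convergence is immediate and
the output is bit-identical for a given config + seed).  Intervals are
truncated below at `0.25·mu/f`.

Two bounds temper the Gaussian idealisation:

- the drift is **clamped at ±2.2 stationary SDs**.  Murine telemetry HR
  envelopes are bounded (registered wild-type extremes of roughly
  310–740 beats/min match the ±2 SD band of the calibrated process); an
  unbounded Gaussian drift occasionally parks the baseline at > 1200
  beats/min for minutes, which no detector should be asked to believe.  The
  clamp censors ~2.7% of drift mass and lowers the drift SD by ~2.5%.
- `ar_phi = 0.998` (relaxation ~500 beats ≈ 60–90 s).  Slower drift leaks
  less into RMSSD but makes 10-min window means wander; this value keeps the
  RMSSD leak ≤ ~3% while 10-min means stay within ~1% of the phase mean.

### Calibration of the packaged baseline scenarios

Phase means and noise SDs are transcribed from the published night/day HRV
table: `sigma_white = RMSSD/sqrt(2)` and `sigma_slow` chosen so the
stationary drift + white variance reproduces SDNN, separately per genotype
and phase (hence the optional night-phase overrides in `ScenarioConfig`).
Arrhythmia injection rates are the published per-24-h averages (wild type:
53 short escapes, 1 long escape, 0.6 AV blocks; knockout: 204, 117, 30).
Premature-beat and tachy-brady rates are described in the source only as
"few (in knockouts)"; the scenarios use nominal 1 / 0.5 (wild type) and
5 / 5 (knockout) per 24 h.  PR (35 ± 1.5 ms) and QT (28 ± 1.5 ms) are
typical murine surface-ECG values; QT is generated independent of RR, so the
QTc correction is exercised by the analysis rather than encoded in the
generator.

### Injected events

Events are placed uniformly in time at Poisson counts (per-24-h rates),
non-overlapping with a 30-beat guard (placements are re-drawn up to 100
times, then error).  All local modifications share the analysis-side
"local normal" estimator (median of the 20 surrounding sinus intervals):

- **escape beats**: one interval replaced by `factor ×` local normal PP,
  the terminating P tagged ectopic; factors drawn U(1.6, 1.9) for short,
  U(2.2, 3.0) for long — clear of the 2× class boundary.  The candidate
  floor (1.5×) and the 2× split are shared constants between generator and
  detector.
- **AV block**: 1–2 extra sinus-morphology P waves inserted evenly into one
  inter-R gap (RR unchanged).
- **premature beats**: one interval shortened to `factor ×` local normal
  (U(0.45, 0.65)) with compensatory lengthening of the next interval, so
  downstream timing is preserved.
- **tachy-brady episodes**: a 10-s splice, first half at `RR = 0.5·mu`,
  second half at `RR = 2.5·mu`, where `mu` is the *phase-mean* RR.  The
  amplitudes are anchored on the phase mean, not the drifting local
  baseline, so that both limbs clear the detector's segment-global ±2 SD
  envelope wherever the drift currently sits; they are deliberately
  stylised — real sick-sinus oscillations are milder, but no amplitudes are
  published, and at the calibrated SDNN (CV ≈ 20%) only swings of this size
  are *defined* as episodes by the ±2 SD rule.  Both the ground-truth
  timestamp and the detection timestamp anchor on **bradycardia onset**
  (first slow beat): the tachycardic limb can fuse with ordinary high-HR
  drift background, the bradycardic limb cannot.

### Drug transients

`f(t)` is 1 before injection, relaxes exponentially (onset τ) to the target
factor, holds through the plateau window, then relaxes back with the
recovery τ.  The plateau effect may be specified as an absolute HR, resolved
against the phase-mean baseline at injection time.  The published challenge
numbers fix the plateau HRs (carbachol 335/448 beats/min for knockout/wild
type; atropine 758/690); effect shapes are stated only as "~1 h", so the τ
values (onset 60 s, plateau 20 min, recovery 10 min for carbachol; slower
for atropine) are free calibration parameters per scenario.  Challenge
scenarios use a reduced drift amplitude (stationary ~6 ms vs ~23–26 ms in
the 24-h scenarios): a short post-handling pharmacological clamp suppresses
the circadian/behavioural variability the baseline SDNN encodes, and the
vehicle-control contract (NaCl extremum within 100 ± 5% of baseline,
duration 0) demands it.

## Analysis choices

- Window-mean HR is `60/(mean RR/1000)` — mean of intervals, then convert;
  per-beat HR averaging is available as an option.  Window QTc uses the same
  window's mean QT and mean RR.  The baseline 10-of-30-min grid is anchored
  at recording start (the anchor is otherwise unspecified).
- The ±2 SD sinus screen uses inclusive bounds, sample SD (n−1), computed
  once per 12-h segment and applied in a single pass (not iterated).
  Successive differences are taken only between retained intervals adjacent
  in the original series.  `|diff|` is used for pNNx, as in standard pNN50
  practice.
- "Local normal" PP/RR is a 20-interval running median of sinus intervals —
  robust against the very pauses being detected; with < 5 usable
  neighbours it falls back to the segment median.
- Escape detection defaults to morphology mode (ectopic P tag = candidate);
  an interval-only mode (pause > 1.5× local normal) serves annotation
  sources without morphology tags.  The short/long split is strict `>` at
  2×, so a pause of exactly two PP intervals classifies short.
- AV block is counted once per inter-R gap regardless of P multiplicity
  (degree recorded as the event detail).
- The tachy-brady rule (±2 SD crossings within 30 s) requires ≥ 3
  consecutive supra/sub-threshold beats per limb.  Without this debounce the
  rule fires on any single noisy beat and on every premature beat + its
  compensatory pause; a minimum run length is the standard telemetry
  debounce.  Thresholds are computed per light-phase segment (falling back
  to the whole recording without clock metadata).  Premature beats inside
  detected episodes are suppressed.
- Drug responses: extremum direction is fixed per drug (min for carbachol /
  atenolol, max for atropine / isoprenaline / NaCl) to avoid sign flips in
  noisy data; the search window is 2 h post injection; effect duration is
  the time to first return within ±5% of baseline after the extremum.
  Baseline is the pre-injection 30-min window of the same session.
- Echo: Teichholz volumes and the uncorrected cubed LV-mass convention
  (density 1.053) are the standard M-mode formulas; the source names
  neither (vendor-internal algorithms), so these are documented constants.
  Inverted measures (LVIDs > LVIDd) warn instead of erroring so batch
  tables survive outliers.
- "Standard t-test" is read as Student's unpaired two-sided (pooled
  variance); Welch and paired variants are flags.  Tukey HSD uses the
  studentized-range distribution; the test suite cross-checks it against an
  independent implementation (statsmodels).  Degenerate zero-variance
  inputs return the limit values (p = 1 for identical groups, p = 0
  otherwise) with a note, rather than NaN.

## What a green test does and does not establish

The generator emulates the *statistical* structure the analyses assume:
circadian phase means, SDNN/RMSSD-calibrated noise, well-separated injected
events, scripted smooth drug transients.  It does not emulate annotation
noise (mislabelled or missed beats), waveform-level QT/PR measurement error
correlated with rate, activity-coupled non-stationarity within a phase, or
overlapping/compound arrhythmias.  Detector precision/recall ≈ 1 on
simulated recordings therefore validates the rule implementations, not
real-world annotation robustness.

Known limitations:

- With `sigma_white` pinned by RMSSD, the Gaussian white-noise model
  *overpredicts* pNN6 (e.g. ≈ 37% vs the published 24% for the wild-type
  day phase): real murine RR-difference distributions are heavier-tailed
  with more sub-6-ms mass than a Gaussian of the same RMSSD.  pNN6 is
  computed and reported but not used for calibration.
- The published genotype-comparison p-values for the HRV table are not
  reproducible from its printed summaries (a summary t-test on the
  night-phase NN row gives p ≈ 0.50 vs the published 0.21; n is inferred
  from SD/SEM ratios and the pairing structure is unstated).  The package
  reproduces the computations, not those specific p-values.
- Tachy-brady amplitudes and the premature threshold (0.75×) have no
  published values; both are configurable constants.
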