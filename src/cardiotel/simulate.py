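"""Synthetic mouse-telemetry generator with ground-truth event labels.

The generator emulates the statistical structure that the downstream analyses
assume in a 24-h murine telemetry recording:

* a circadian two-phase RR baseline (distinct day/night phase means),
* beat-to-beat white noise plus an AR(1) slow drift (the simplest process
  with independently tunable SDNN and RMSSD),
* Poisson-injected arrhythmia events of five classes (short/long atrial
  escape beats, AV block, premature beats, tachy-brady episodes), each
  recorded in a ground-truth table,
* scripted pharmacological HR transients (exponential onset, plateau,
  exponential recovery) that multiply heart rate, i.e. divide RR.

Per beat the RR interval is

    RR_i = mu(phase(t_i)) / f(t_i) + d_i + w_i,     truncated at 0.25 mu/f,

with ``f`` the combined drug HR factor, ``d`` the AR(1) drift
(d_i = phi d_{i-1} + eps_i, eps ~ N(0, sigma_slow)) and ``w ~ N(0,
sigma_white)``.  Because ``t_i`` itself depends on the preceding intervals,
the self-consistent beat times are obtained by a short fixed-point iteration
(the modulating signals vary on >=60 s scales, so convergence is immediate).
Identical configuration + seed gives bit-identical output.

Each R peak is preceded by a P wave at lag ``pr_ms``; escape beats tag that
P as ``ectopic``, AV blocks insert extra (conducted-morphology) P waves into
an inter-R gap, premature beats shorten one interval with a compensatory
pause, and tachy-brady episodes splice in a scripted high->low HR ramp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .beats import Recording, build_phase_windows, phase_of_times
from .errors import ConfigurationError, DomainError, PlacementError

EVENT_CLASSES = ("escape_short", "escape_long", "av_block", "premature", "tachy_brady")

#: lower pause bound (in units of the local normal PP) below which a beat is
#: not considered an escape candidate; shared by generator and detector.
ESCAPE_CANDIDATE_FACTOR = 1.5
#: short/long escape split, in units of the local normal PP
ESCAPE_LONG_FACTOR = 2.0
#: premature-beat threshold, in units of the local normal RR
PREMATURE_FACTOR = 0.75

#: the slow baseline drift is clamped at this many stationary SDs.  Telemetry
#: HR envelopes are bounded (registered murine extremes span roughly the
#: +/-2 SD band of the calibrated RR process); an unbounded Gaussian drift
#: would occasionally park the baseline at physiologically impossible rates.
DRIFT_CLIP_SD = 2.2


# ---------------------------------------------------------------------------
# Drug transients
# ---------------------------------------------------------------------------

KNOWN_DRUGS = ("NaCl", "atropine", "carbachol", "isoprenaline", "atenolol")


@dataclass
class DrugEvent:
    """One scheduled injection and its scripted HR transient.

    The plateau effect size may be given either as a multiplicative HR factor
    (``target_factor``) or as an absolute plateau heart rate
    (``target_hr_bpm``), which is resolved against the phase-mean baseline HR
    at injection time.
    """

    drug: str
    t_injection_s: float
    target_factor: float | None = None
    target_hr_bpm: float | None = None
    tau_onset_s: float = 60.0
    plateau_s: float = 1200.0
    tau_recovery_s: float = 600.0

    def validate(self) -> None:
        if self.drug not in KNOWN_DRUGS:
            raise ConfigurationError(f"unknown drug {self.drug!r}")
        if (self.target_factor is None) == (self.target_hr_bpm is None):
            raise ConfigurationError(
                "exactly one of target_factor / target_hr_bpm must be set"
            )
        if self.t_injection_s < 0 or self.plateau_s < 0:
            raise ConfigurationError("negative injection time or plateau")
        if self.tau_onset_s <= 0 or self.tau_recovery_s <= 0:
            raise ConfigurationError("time constants must be positive")

    def resolve_factor(self, baseline_hr_bpm: float | None = None) -> float:
        if self.target_factor is not None:
            return float(self.target_factor)
        if baseline_hr_bpm is None:
            raise ConfigurationError(
                "target_hr_bpm needs a baseline HR to resolve the factor"
            )
        return float(self.target_hr_bpm) / float(baseline_hr_bpm)


def drug_hr_factor(t_s, entry: DrugEvent, baseline_hr_bpm: float | None = None):
    """Multiplicative HR factor of one schedule entry at time(s) ``t_s``.

    1 before injection; exponential approach (onset tau) to the target factor
    during the plateau window; exponential relaxation back to 1 afterwards.
    The factor multiplies HR, i.e. divides RR.
    """
    entry.validate()
    target = entry.resolve_factor(baseline_hr_bpm)
    t = np.asarray(t_s, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    t0 = entry.t_injection_s
    t1 = t0 + entry.plateau_s
    f = np.ones_like(t)
    hold = (t >= t0) & (t < t1)
    f[hold] = target + (1.0 - target) * np.exp(-(t[hold] - t0) / entry.tau_onset_s)
    f_end = target + (1.0 - target) * np.exp(-entry.plateau_s / entry.tau_onset_s)
    after = t >= t1
    f[after] = 1.0 + (f_end - 1.0) * np.exp(-(t[after] - t1) / entry.tau_recovery_s)
    return float(f[0]) if scalar else f


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic recording.

    ``sigma_slow_ms`` is the AR(1) *innovation* SD; the stationary SD of the
    drift is ``sigma_slow_ms / sqrt(1 - ar_phi**2)``, so the expected SDNN of
    the clean process is ``sqrt(sigma_white**2 + sigma_slow**2/(1-phi**2))``
    and the expected RMSSD is ``~ sigma_white * sqrt(2)`` for ``phi -> 1``.
    Night-phase noise overrides fall back to the day values when unset.
    """

    mu_rr_day_ms: float = 120.0
    mu_rr_night_ms: float = 110.0
    sigma_white_ms: float = 4.0
    ar_phi: float = 0.998
    sigma_slow_ms: float = 1.5
    sigma_white_night_ms: float | None = None
    sigma_slow_night_ms: float | None = None
    pr_mean_ms: float = 35.0
    pr_sd_ms: float = 1.5
    qt_mean_ms: float = 28.0
    qt_sd_ms: float = 1.5
    event_rates_per_24h: dict = field(default_factory=dict)
    drug_schedule: list = field(default_factory=list)
    duration_h: float = 24.0
    lights_on_clock: str = "07:00"
    t0_clock: str = "07:00"
    seed: int = 0
    genotype: str = "wt"
    animal_id: str = "sim"
    # injected-event parameter ranges (drawn uniformly per event)
    escape_short_factor: tuple = (1.6, 1.9)
    escape_long_factor: tuple = (2.2, 3.0)
    av_block_extra_p: tuple = (1, 2)
    premature_factor: tuple = (0.45, 0.65)
    tachy_high_rr_factor: float = 0.5
    tachy_low_rr_factor: float = 2.5
    tachy_span_s: float = 10.0

    def __post_init__(self) -> None:
        self.drug_schedule = [
            d if isinstance(d, DrugEvent) else DrugEvent(**d) for d in self.drug_schedule
        ]

    def validate(self) -> None:
        if self.mu_rr_day_ms <= 0 or self.mu_rr_night_ms <= 0:
            raise ConfigurationError("phase mean RR must be positive")
        for name in ("sigma_white_ms", "sigma_slow_ms", "pr_sd_ms", "qt_sd_ms"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("sigma_white_night_ms", "sigma_slow_night_ms"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.pr_mean_ms <= 0 or self.qt_mean_ms <= 0:
            raise ConfigurationError("pr/qt means must be positive")
        if not abs(self.ar_phi) < 1:
            raise ConfigurationError("|ar_phi| must be < 1")
        if self.duration_h <= 0:
            raise ConfigurationError("duration_h must be positive")
        for cls, rate in self.event_rates_per_24h.items():
            if cls not in EVENT_CLASSES:
                raise ConfigurationError(f"unknown event class {cls!r}")
            if rate < 0:
                raise ConfigurationError(f"negative rate for {cls}")
        for entry in self.drug_schedule:
            entry.validate()
        lo, hi = self.escape_short_factor
        if not (ESCAPE_CANDIDATE_FACTOR < lo <= hi <= ESCAPE_LONG_FACTOR):
            raise ConfigurationError("escape_short_factor must lie in (1.5, 2]")
        lo, hi = self.escape_long_factor
        if not (ESCAPE_LONG_FACTOR < lo <= hi):
            raise ConfigurationError("escape_long_factor must exceed 2")
        lo, hi = self.premature_factor
        if not (0 < lo <= hi < PREMATURE_FACTOR):
            raise ConfigurationError("premature_factor must lie in (0, 0.75)")
        if not 0 < self.tachy_high_rr_factor < 1 < self.tachy_low_rr_factor:
            raise ConfigurationError("tachy RR factors must bracket 1")
        if not 0 < self.tachy_span_s <= 30:
            raise ConfigurationError("tachy_span_s must lie in (0, 30]")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_schedule"] = [asdict(e) for e in self.drug_schedule]
        for key in ("escape_short_factor", "escape_long_factor",
                    "av_block_extra_p", "premature_factor"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("escape_short_factor", "escape_long_factor",
                    "av_block_extra_p", "premature_factor"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown scenario keys {sorted(unknown)}")
        return cls(**d)


def save_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def packaged_scenarios() -> list[str]:
    """Names of the scenario configs shipped with the package."""
    base = resources.files("cardiotel") / "scenarios"
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path, **overrides) -> ScenarioConfig:
    """Load a scenario config from a YAML path or a packaged scenario name."""
    if isinstance(name_or_path, (str, os.PathLike)) and os.path.exists(name_or_path):
        with open(name_or_path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        res = resources.files("cardiotel") / "scenarios" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise ConfigurationError(
                f"unknown scenario {name_or_path!r}; packaged: {packaged_scenarios()}"
            )
        data = yaml.safe_load(res.read_text(encoding="utf-8"))
    data.update(overrides)
    return ScenarioConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Mutable beat buffer and event injectors
# ---------------------------------------------------------------------------


@dataclass
class BeatFrame:
    """Mutable array view of a beat sequence used during event injection.

    ``rr_ms[i]`` is the interval between beats ``i`` and ``i+1``; ``morph``,
    ``pr_ms`` and ``qt_ms`` are per-beat (length ``n_beats``); ``av_extra``
    maps an interval index to the number of extra (non-conducted) P waves in
    that inter-R gap.
    """

    t_first_s: float
    rr_ms: np.ndarray
    morph: np.ndarray
    pr_ms: np.ndarray
    qt_ms: np.ndarray
    av_extra: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return len(self.rr_ms) + 1

    def r_times_s(self) -> np.ndarray:
        return self.t_first_s + np.concatenate(
            ([0.0], np.cumsum(self.rr_ms) / 1000.0)
        )

    def local_normal_ms(self, index: int, half_window: int = 10) -> float:
        """Median of the surrounding intervals, excluding ``index`` itself.

        Falls back to the whole-segment median when fewer than 5 neighbours
        are available.
        """
        lo = max(0, index - half_window)
        vals = np.concatenate(
            (self.rr_ms[lo:index], self.rr_ms[index + 1 : index + 1 + half_window])
        )
        if vals.size < 5:
            return float(np.median(self.rr_ms))
        return float(np.median(vals))

    @classmethod
    def from_recording(cls, recording: Recording) -> "BeatFrame":
        ev = recording.events
        t = ev["time_s"].to_numpy(float)
        is_r = (ev["kind"] == "R").to_numpy()
        r_idx = np.flatnonzero(is_r)
        r_t = t[r_idx]
        if r_t.size < 2:
            raise ConfigurationError("need >= 2 R events to build a BeatFrame")
        morphs = ev["morph"].to_numpy()
        # conducted P of each beat = last P event before (or at) the R peak
        p_idx = np.flatnonzero(~is_r)
        p_t = t[p_idx]
        beat_morph = np.full(r_t.size, "sinus", dtype=object)
        if p_t.size:
            pos = np.searchsorted(p_t, r_t, side="right") - 1
            ok = pos >= 0
            beat_morph[ok] = morphs[p_idx[pos[ok]]]
        return cls(
            t_first_s=float(r_t[0]),
            rr_ms=np.diff(r_t) * 1000.0,
            morph=beat_morph,
            pr_ms=ev.loc[is_r, "pr_ms"].to_numpy(float),
            qt_ms=ev.loc[is_r, "qt_ms"].to_numpy(float),
        )

    def to_recording(self, duration_s: float | None = None, **meta) -> Recording:
        r_t = self.r_times_s()
        pr = self.pr_ms.copy()
        nan_pr = np.isnan(pr)
        pr[nan_pr] = 1.0
        # keep each conducted P inside its own inter-R gap (and after t=0)
        pr[0] = min(pr[0], 0.8 * self.t_first_s * 1000.0)
        pr[1:] = np.minimum(pr[1:], 0.8 * self.rr_ms)
        p_t = r_t - pr / 1000.0
        pr[nan_pr] = np.nan

        extra_t, extra_m = [], []
        for i, k in self.av_extra.items():
            gap_lo, gap_hi = r_t[i], p_t[i + 1]
            for j in range(k):
                extra_t.append(gap_lo + (gap_hi - gap_lo) * (j + 1) / (k + 1))
                extra_m.append("sinus")
        n = len(r_t)
        times = np.concatenate((p_t, np.asarray(extra_t, float), r_t))
        kinds = np.concatenate(
            (np.full(n + len(extra_t), "P", object), np.full(n, "R", object))
        )
        morphs = np.concatenate((self.morph, np.asarray(extra_m, object),
                                 np.full(n, "na", object)))
        pr_col = np.concatenate((np.full(n + len(extra_t), np.nan), pr))
        qt_col = np.concatenate((np.full(n + len(extra_t), np.nan), self.qt_ms))
        order = np.lexsort((kinds == "R", times))
        df = pd.DataFrame(
            {
                "time_s": times[order],
                "kind": kinds[order],
                "morph": morphs[order],
                "pr_ms": pr_col[order],
                "qt_ms": qt_col[order],
            }
        )
        if duration_s is None:
            duration_s = float(r_t[-1]) + 1.0
        rec = Recording(events=df, duration_s=duration_s, **meta)
        rec.validate()
        return rec


def inject_escape_beat(
    frame: BeatFrame,
    index: int,
    length_factor: float,
    variant: str,
    local_pp_ms: float | None = None,
) -> dict:
    """Replace interval ``index`` by an atrial escape pause.

    The pause is ``length_factor`` x the local normal PP and the terminating
    beat's P wave is tagged ``ectopic`` (it sits late in the pause, at its
    usual PR lag before the R).  Returns the ground-truth row.
    """
    if variant == "long":
        if not length_factor > ESCAPE_LONG_FACTOR:
            raise DomainError("long escape requires length_factor > 2")
    elif variant == "short":
        if not ESCAPE_CANDIDATE_FACTOR < length_factor <= ESCAPE_LONG_FACTOR:
            raise DomainError("short escape requires 1.5 < length_factor <= 2")
    else:
        raise DomainError(f"unknown escape variant {variant!r}")
    if not 0 <= index < len(frame.rr_ms):
        raise PlacementError(f"interval index {index} out of range")
    local = frame.local_normal_ms(index) if local_pp_ms is None else local_pp_ms
    frame.rr_ms[index] = length_factor * local
    frame.morph[index + 1] = "ectopic"
    return {
        "beat_index": index + 1,
        "event_class": f"escape_{variant}",
        "param": float(length_factor),
    }


def inject_av_block(frame: BeatFrame, index: int, extra_p: int) -> dict:
    """Insert ``extra_p`` non-conducted P waves into inter-R gap ``index``."""
    if extra_p < 1:
        raise DomainError("extra_p must be >= 1")
    if not 0 <= index < len(frame.rr_ms):
        raise PlacementError(f"interval index {index} out of range")
    if index in frame.av_extra:
        raise PlacementError(f"interval {index} already carries an AV block")
    frame.av_extra[index] = int(extra_p)
    return {
        "beat_index": index + 1,
        "event_class": "av_block",
        "param": float(extra_p),
    }


def inject_premature_beat(
    frame: BeatFrame,
    index: int,
    shortening_factor: float,
    local_rr_ms: float | None = None,
) -> dict:
    """Shorten interval ``index`` to ``factor`` x local normal RR with a
    compensatory lengthening of the next interval (downstream timing kept)."""
    if not 0 < shortening_factor < PREMATURE_FACTOR:
        raise DomainError("shortening_factor must lie in (0, 0.75)")
    if not 0 <= index < len(frame.rr_ms) - 1:
        raise PlacementError("premature beat needs a following interval")
    local = frame.local_normal_ms(index) if local_rr_ms is None else local_rr_ms
    removed = frame.rr_ms[index] - shortening_factor * local
    frame.rr_ms[index] = shortening_factor * local
    frame.rr_ms[index + 1] += removed
    return {
        "beat_index": index + 1,
        "event_class": "premature",
        "param": float(shortening_factor),
    }


def inject_tachy_brady_episode(
    frame: BeatFrame,
    index: int,
    high_hr_bpm: float,
    low_hr_bpm: float,
    span_s: float,
    baseline_hr_bpm: float,
    rng: np.random.Generator,
    pr_ms: tuple[float, float] = (35.0, 1.5),
    qt_ms: tuple[float, float] = (28.0, 1.5),
) -> tuple[dict, int]:
    """Splice a high->low HR ramp over ``span_s`` starting at beat ``index``.

    First half of the span at ``60000/high_hr`` ms, second half at
    ``60000/low_hr`` ms.  Returns (truth row, change in beat count).
    """
    if not high_hr_bpm > baseline_hr_bpm > low_hr_bpm:
        raise DomainError("need high_hr > baseline HR > low_hr")
    if not 0 < span_s <= 30:
        raise DomainError("span_s must lie in (0, 30]")
    rr_high = 60000.0 / high_hr_bpm
    rr_low = 60000.0 / low_hr_bpm
    n_high = int(round(span_s * 500.0 / rr_high))
    n_low = int(round(span_s * 500.0 / rr_low))
    if n_high < 2 or n_low < 2:
        raise PlacementError("span too short for 2 beats per limb")
    # old intervals covered by the span
    cum = np.cumsum(frame.rr_ms[index:]) / 1000.0
    m = int(np.searchsorted(cum, span_s)) + 1
    if index + m > len(frame.rr_ms):
        raise PlacementError("episode does not fit before end of recording")
    new_rr = np.concatenate((np.full(n_high, rr_high), np.full(n_low, rr_low)))
    n_new_beats = len(new_rr) - 1
    frame.rr_ms = np.concatenate(
        (frame.rr_ms[:index], new_rr, frame.rr_ms[index + m :])
    )
    mid_morph = np.full(n_new_beats, "sinus", dtype=object)
    mid_pr = rng.normal(pr_ms[0], pr_ms[1], n_new_beats).clip(min=1.0)
    mid_qt = rng.normal(qt_ms[0], qt_ms[1], n_new_beats).clip(min=1.0)
    frame.morph = np.concatenate((frame.morph[: index + 1], mid_morph, frame.morph[index + m :]))
    frame.pr_ms = np.concatenate((frame.pr_ms[: index + 1], mid_pr, frame.pr_ms[index + m :]))
    frame.qt_ms = np.concatenate((frame.qt_ms[: index + 1], mid_qt, frame.qt_ms[index + m :]))
    delta = len(new_rr) - m
    # keep AV-block gap indices aligned with the spliced interval array
    frame.av_extra = {
        (i + delta if i >= index + m else i): k for i, k in frame.av_extra.items()
    }
    # the truth timestamp anchors on bradycardia onset (first slow beat):
    # the tachycardic limb can fuse with ordinary high-HR background, the
    # bradycardic limb cannot, so this anchor is what a detector can match
    truth = {
        "beat_index": index + n_high,
        "event_class": "tachy_brady",
        "param": float(span_s),
    }
    return truth, delta


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


@dataclass
class TruthEventTable:
    """Ground-truth injected events: ``time_s, event_class, param``."""

    df: pd.DataFrame

    @classmethod
    def empty(cls) -> "TruthEventTable":
        return cls(pd.DataFrame(columns=["time_s", "event_class", "param"]))

    def __len__(self) -> int:
        return len(self.df)

    def counts(self) -> dict:
        c = self.df["event_class"].value_counts().to_dict()
        return {cls: int(c.get(cls, 0)) for cls in EVENT_CLASSES}

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def read_csv(cls, path) -> "TruthEventTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

_GUARD_BEATS = 30  # minimum index separation between injected point events


def _planned_extent(cls: str, config: ScenarioConfig) -> int:
    """Number of beats an injected event may perturb (for overlap checks)."""
    if cls == "tachy_brady":
        mu_min = min(config.mu_rr_day_ms, config.mu_rr_night_ms)
        return int(np.ceil(config.tachy_span_s * 1000.0 / (mu_min * config.tachy_high_rr_factor))) + _GUARD_BEATS
    return _GUARD_BEATS


def generate_recording(config: ScenarioConfig) -> tuple[Recording, TruthEventTable]:
    """Simulate one annotated recording plus its ground-truth event table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    duration_s = config.duration_h * 3600.0
    windows = build_phase_windows(config.lights_on_clock, config.t0_clock, duration_s)

    phi = config.ar_phi
    sw_day = config.sigma_white_ms
    sw_night = (config.sigma_white_night_ms
                if config.sigma_white_night_ms is not None else sw_day)
    si_day = config.sigma_slow_ms
    si_night = (config.sigma_slow_night_ms
                if config.sigma_slow_night_ms is not None else si_day)

    max_factor = 1.0
    for entry in config.drug_schedule:
        day0 = bool(phase_of_times(np.array([entry.t_injection_s]), windows)[0])
        mu0 = config.mu_rr_day_ms if day0 else config.mu_rr_night_ms
        entry._resolved_factor = entry.resolve_factor(60000.0 / mu0)
        max_factor = max(max_factor, entry._resolved_factor)

    mu_min = min(config.mu_rr_day_ms, config.mu_rr_night_ms)
    n_max = int(duration_s * 1000.0 / mu_min * max_factor * 1.15) + 256
    white_u = rng.standard_normal(n_max)
    inn_u = rng.standard_normal(n_max)
    drift0_u = rng.standard_normal()

    t_first = 0.2
    t_start = np.full(n_max, t_first)
    stat0 = (si_day if windows[0].label == "day" else si_night) / np.sqrt(1 - phi**2)
    rr = None
    for _ in range(4):
        day = phase_of_times(t_start, windows)
        mu = np.where(day, config.mu_rr_day_ms, config.mu_rr_night_ms)
        sw = np.where(day, sw_day, sw_night)
        si = np.where(day, si_day, si_night)
        drift, _ = lfilter([1.0], [1.0, -phi], inn_u * si, zi=[phi * drift0_u * stat0])
        stat = si / np.sqrt(1 - phi**2)
        drift = np.clip(drift, -DRIFT_CLIP_SD * stat, DRIFT_CLIP_SD * stat)
        f = np.ones(n_max)
        for entry in config.drug_schedule:
            resolved = DrugEvent(
                drug=entry.drug,
                t_injection_s=entry.t_injection_s,
                target_factor=entry._resolved_factor,
                tau_onset_s=entry.tau_onset_s,
                plateau_s=entry.plateau_s,
                tau_recovery_s=entry.tau_recovery_s,
            )
            f = f * drug_hr_factor(t_start, resolved)
        base = mu / f
        rr = base + drift + white_u * sw
        rr = np.maximum(rr, 0.25 * base)
        t_start = t_first + np.concatenate(([0.0], np.cumsum(rr[:-1]) / 1000.0))

    n_beats = int(np.searchsorted(t_start, duration_s))
    if n_beats < 2:
        raise ConfigurationError("recording too short to contain two beats")
    if n_beats >= n_max:  # pragma: no cover - headroom is generous
        raise RuntimeError("beat buffer exhausted")
    rr = rr[: n_beats - 1]
    frame = BeatFrame(
        t_first_s=t_first,
        rr_ms=rr.copy(),
        morph=np.full(n_beats, "sinus", dtype=object),
        pr_ms=rng.normal(config.pr_mean_ms, config.pr_sd_ms, n_beats).clip(min=1.0),
        qt_ms=rng.normal(config.qt_mean_ms, config.qt_sd_ms, n_beats).clip(min=1.0),
    )

    # --- plan injections ----------------------------------------------------
    plan = []
    occupied: list[tuple[int, int]] = []  # (index, extent)
    n_int = len(frame.rr_ms)
    for cls in EVENT_CLASSES:
        rate = float(config.event_rates_per_24h.get(cls, 0.0))
        count = int(rng.poisson(rate * config.duration_h / 24.0))
        extent = _planned_extent(cls, config)
        for _ in range(count):
            lo, hi = _GUARD_BEATS, n_int - extent - 1
            if hi <= lo:
                raise PlacementError("recording too short for injected events")
            for _try in range(100):
                idx = int(rng.integers(lo, hi))
                if all(
                    idx + extent + _GUARD_BEATS < p or p + pe + _GUARD_BEATS < idx
                    for p, pe in occupied
                ):
                    break
            else:
                raise PlacementError(f"could not place {cls} event after 100 tries")
            occupied.append((idx, extent))
            if cls == "escape_short":
                params = ("short", float(rng.uniform(*config.escape_short_factor)))
            elif cls == "escape_long":
                params = ("long", float(rng.uniform(*config.escape_long_factor)))
            elif cls == "av_block":
                lo_p, hi_p = config.av_block_extra_p
                params = (int(rng.integers(lo_p, hi_p + 1)),)
            elif cls == "premature":
                params = (float(rng.uniform(*config.premature_factor)),)
            else:  # tachy_brady
                params = ()
            plan.append((idx, cls, params))

    # --- apply, highest index first so splices do not shift pending indices --
    plan.sort(key=lambda e: -e[0])
    truth_rows: list[dict] = []
    for idx, cls, params in plan:
        if cls in ("escape_short", "escape_long"):
            variant, factor = params
            row = inject_escape_beat(frame, idx, factor, variant)
        elif cls == "av_block":
            row = inject_av_block(frame, idx, params[0])
        elif cls == "premature":
            row = inject_premature_beat(frame, idx, params[0])
        else:
            # episode amplitude anchored on the *phase mean* RR (not the
            # drifting local baseline) so both limbs clear the segment-wide
            # +/-2 SD detection envelope wherever the drift currently sits
            t_idx = frame.t_first_s + float(np.sum(frame.rr_ms[:idx])) / 1000.0
            is_day = bool(phase_of_times(np.array([t_idx]), windows)[0])
            mu_here = config.mu_rr_day_ms if is_day else config.mu_rr_night_ms
            high_hr = 60000.0 / (config.tachy_high_rr_factor * mu_here)
            low_hr = 60000.0 / (config.tachy_low_rr_factor * mu_here)
            row, delta = inject_tachy_brady_episode(
                frame,
                idx,
                high_hr,
                low_hr,
                config.tachy_span_s,
                baseline_hr_bpm=60000.0 / mu_here,
                rng=rng,
                pr_ms=(config.pr_mean_ms, config.pr_sd_ms),
                qt_ms=(config.qt_mean_ms, config.qt_sd_ms),
            )
            for prev in truth_rows:  # all pending rows sit above the splice
                prev["beat_index"] += delta
        truth_rows.append(row)

    r_times = frame.r_times_s()
    # a splice may push the tail past duration_s; trim trailing beats
    keep = int(np.searchsorted(r_times, duration_s))
    if keep < frame.n_beats:
        frame.rr_ms = frame.rr_ms[: keep - 1]
        frame.morph = frame.morph[:keep]
        frame.pr_ms = frame.pr_ms[:keep]
        frame.qt_ms = frame.qt_ms[:keep]
        frame.av_extra = {i: k for i, k in frame.av_extra.items() if i < keep - 1}
        truth_rows = [r for r in truth_rows if r["beat_index"] < keep]
        r_times = frame.r_times_s()

    truth_df = pd.DataFrame(
        [
            {
                "time_s": float(r_times[row["beat_index"]]),
                "event_class": row["event_class"],
                "param": row["param"],
            }
            for row in truth_rows
        ],
        columns=["time_s", "event_class", "param"],
    ).sort_values("time_s", ignore_index=True)

    recording = frame.to_recording(
        duration_s=duration_s,
        animal_id=config.animal_id,
        genotype=config.genotype,
        lights_on_clock=config.lights_on_clock,
        t0_clock=config.t0_clock,
    )
    return recording, TruthEventTable(truth_df)
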