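"""Rule-based detection and counting of sinus-node / conduction arrhythmias.

Four event classes are recognised from annotated beat streams:

* ``escape_short`` / ``escape_long`` -- atrial escape beats: a pause ended by
  a beat whose P wave has non-sinus (ectopic) morphology; *long* if the pause
  exceeds twice the local normal P-P interval (strict), *short* otherwise.
  In interval-only mode (no morphology tags) any pause > 1.5x the local
  normal P-P is a candidate; the 1.5x lower bound separates candidate pauses
  from ordinary variability and is shared with the generator.
* ``av_block`` -- more than one P wave within a single inter-R gap (counted
  once per gap; the P multiplicity is recorded as the event detail).
* ``premature`` -- an interval shorter than 0.75x the local normal RR
  (strict), outside tachy-brady episodes.
* ``tachy_brady`` -- instantaneous HR exceeding the segment mean + 2 SD and
  subsequently falling below mean - 2 SD within a 30-s window, each limb
  sustained for at least ``min_run`` consecutive beats (debouncing against
  single noisy beats and premature/compensatory pairs); overlapping episodes
  merge.

"Local normal" intervals are running medians (robust against the very pauses
being detected) over a 20-interval neighbourhood of sinus-conducted beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import Recording, segment_phases
from .errors import ConfigurationError, InsufficientDataError
from .simulate import (
    ESCAPE_CANDIDATE_FACTOR,
    ESCAPE_LONG_FACTOR,
    EVENT_CLASSES,
    PREMATURE_FACTOR,
    TruthEventTable,
)

EVENT_TABLE_COLUMNS = ["time_s", "event_class", "detail"]


@dataclass
class ArrhythmiaEvent:
    time_s: float
    event_class: str
    detail: float = np.nan

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ConfigurationError(f"unknown event class {self.event_class!r}")


@dataclass
class ArrhythmiaCounts:
    """Per-class raw counts and counts normalised to a 24-h span."""

    raw: dict
    per_24h: dict
    span_h: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_class": list(EVENT_CLASSES),
                "count": [self.raw[c] for c in EVENT_CLASSES],
                "count_per_24h": [self.per_24h[c] for c in EVENT_CLASSES],
            }
        )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_TABLE_COLUMNS).astype(
        {"time_s": float, "detail": float}
    )


class _BeatView:
    """Array-level view of a recording's beats, shared by the detectors."""

    def __init__(self, recording: Recording):
        ev = recording.events
        t = ev["time_s"].to_numpy(float)
        is_r = (ev["kind"] == "R").to_numpy()
        self.r_t = t[is_r]
        if self.r_t.size < 3:
            raise InsufficientDataError("need >= 3 R events for arrhythmia analysis")
        self.rr = np.diff(self.r_t) * 1000.0
        morphs = ev["morph"].to_numpy()
        p_idx = np.flatnonzero(~is_r)
        self.p_t = t[p_idx]
        self.p_morph = morphs[p_idx]
        # conducted P (last P at or before each R) gives the beat morphology
        self.beat_morph = np.full(self.r_t.size, "sinus", dtype=object)
        if self.p_t.size:
            pos = np.searchsorted(self.p_t, self.r_t, side="right") - 1
            ok = pos >= 0
            self.beat_morph[ok] = self.p_morph[pos[ok]]
        # P waves per inter-R gap (gap i = (r_{i-1}, r_i]; gap 0 = (-inf, r_0])
        edges = np.searchsorted(self.p_t, self.r_t, side="right")
        self.p_per_gap = np.diff(np.concatenate(([0], edges)))
        self.sinus_p_t = self.p_t[self.p_morph == "sinus"]

    def local_pp(self, beat_index: int, window: int = 20) -> float:
        """Running median of sinus P-P intervals around a beat."""
        sp = self.sinus_p_t
        if sp.size < 2:
            return float(np.median(self.rr))
        pp = np.diff(sp) * 1000.0
        pos = int(np.searchsorted(sp, self.r_t[beat_index])) - 1
        half = window // 2
        lo = max(0, pos - half)
        vals = np.concatenate((pp[lo:pos], pp[pos + 1 : pos + 1 + half]))
        if vals.size < 5:
            return float(np.median(pp)) if pp.size else float(np.median(self.rr))
        return float(np.median(vals))

    def local_rr(self, window: int = 21) -> np.ndarray:
        """Centred running median of RR, one value per interval."""
        s = pd.Series(self.rr)
        return s.rolling(window, center=True, min_periods=5).median().to_numpy()


def local_normal_pp(recording: Recording, beat_index: int, window: int = 20) -> float:
    """Local normal P-P interval (ms) around beat ``beat_index``: running
    median of sinus P-P intervals in a ``window``-interval neighbourhood,
    falling back to the segment median when fewer than 5 are available."""
    return _BeatView(recording).local_pp(beat_index, window)


def detect_escape_beats(recording: Recording, mode: str = "morph") -> pd.DataFrame:
    """Atrial escape beats, classified short/long at 2x the local normal PP.

    ``mode='morph'`` (default) takes ectopic P morphology as the candidate
    criterion; ``mode='interval'`` flags any pause > 1.5x local normal PP,
    for annotation sources without morphology tags.
    """
    view = _BeatView(recording)
    rows = []
    if mode == "morph":
        candidates = np.flatnonzero(view.beat_morph == "ectopic")
        candidates = candidates[candidates >= 1]
    elif mode == "interval":
        local = view.local_rr()
        pause_ratio = view.rr / local
        candidates = np.flatnonzero(pause_ratio > ESCAPE_CANDIDATE_FACTOR) + 1
    else:
        raise ConfigurationError(f"unknown escape detection mode {mode!r}")
    for i in candidates:
        pause = view.rr[i - 1]
        local = view.local_pp(int(i))
        if mode == "interval" and not pause > ESCAPE_CANDIDATE_FACTOR * local:
            continue
        cls = "escape_long" if pause > ESCAPE_LONG_FACTOR * local else "escape_short"
        rows.append((float(view.r_t[i]), cls, float(pause)))
    return pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS) if rows else _empty_events()


def detect_av_blocks(recording: Recording) -> pd.DataFrame:
    """AV block events: one per inter-R gap holding >= 2 P waves; the detail
    records the P count (block degree)."""
    view = _BeatView(recording)
    idx = np.flatnonzero(view.p_per_gap >= 2)
    if idx.size == 0:
        return _empty_events()
    return pd.DataFrame(
        {
            "time_s": view.r_t[idx],
            "event_class": "av_block",
            "detail": view.p_per_gap[idx].astype(float),
        }
    )


def detect_premature_beats(
    recording: Recording,
    threshold: float = PREMATURE_FACTOR,
    exclude_spans: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Premature beats: RR < ``threshold`` x local normal RR (strict),
    excluding beats inside the given (tachy-brady) episode spans."""
    view = _BeatView(recording)
    local = view.local_rr()
    with np.errstate(invalid="ignore"):
        cand = np.flatnonzero(view.rr < threshold * local)
    rows = []
    for i in cand:
        t_beat = float(view.r_t[i + 1])
        if exclude_spans and any(lo <= t_beat <= hi for lo, hi in exclude_spans):
            continue
        rows.append((t_beat, "premature", float(view.rr[i])))
    return pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS) if rows else _empty_events()


def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as [start, end) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def detect_tachy_brady(
    recording: Recording,
    high_z: float = 2.0,
    low_z: float = 2.0,
    span_s: float = 30.0,
    min_run: int = 3,
    return_spans: bool = False,
):
    """Tachycardia-followed-by-bradycardia episodes.

    Within each light-phase segment, instantaneous HR (60000/RR) must first
    exceed the segment mean + ``high_z`` SD and subsequently fall below the
    mean - ``low_z`` SD within ``span_s`` seconds, each limb holding for at
    least ``min_run`` consecutive beats; overlapping episodes merge.
    """
    view = _BeatView(recording)
    hr = 60000.0 / view.rr
    t0 = view.r_t[:-1]
    try:
        segments = [(w.t_start_s, w.t_end_s) for w in segment_phases(recording)]
    except ConfigurationError:
        segments = [(float(view.r_t[0]), float(view.r_t[-1]) + 1.0)]

    episodes: list[tuple[float, float]] = []
    for lo, hi in segments:
        sel = (t0 >= lo) & (t0 < hi)
        if sel.sum() < max(min_run * 2, 10):
            continue
        seg_hr = hr[sel]
        seg_t = t0[sel]
        m, s = seg_hr.mean(), seg_hr.std(ddof=1)
        if s == 0:
            continue
        high_runs = _runs(seg_hr > m + high_z * s, min_run)
        low_runs = _runs(seg_hr < m - low_z * s, min_run)
        # each bradycardic run pairs with the latest preceding (unused)
        # tachycardic run ending no more than span_s before it; the event
        # timestamp is bradycardia onset, the most clear-cut anchor
        used = np.zeros(len(high_runs), dtype=bool)
        high_ends = np.array([seg_t[h1 - 1] for _, h1 in high_runs])
        for l0, l1 in low_runs:
            t_low = seg_t[l0]
            cand = np.flatnonzero((~used) & (high_ends < t_low)
                                  & (high_ends >= t_low - span_s))
            if cand.size == 0:
                continue
            h = int(cand[-1])
            used[h] = True
            episodes.append(
                (float(t_low), float(seg_t[high_runs[h][0]]), float(seg_t[l1 - 1]))
            )
    # merge episodes with overlapping spans
    episodes.sort(key=lambda e: e[1])
    merged: list[list[float]] = []
    for t_ev, a, b in episodes:
        if merged and a <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], b)
        else:
            merged.append([t_ev, a, b])
    if not merged:
        return (_empty_events(), []) if return_spans else _empty_events()
    df = pd.DataFrame(
        {
            "time_s": [t_ev for t_ev, _, _ in merged],
            "event_class": "tachy_brady",
            "detail": [b - a for _, a, b in merged],
        }
    )
    spans = [(a, b) for _, a, b in merged]
    return (df, spans) if return_spans else df


def detect_arrhythmias(recording: Recording, escape_mode: str = "morph") -> pd.DataFrame:
    """Run all four detectors and return the combined, time-sorted event table."""
    tachy, spans = detect_tachy_brady(recording, return_spans=True)
    parts = [
        detect_escape_beats(recording, mode=escape_mode),
        detect_av_blocks(recording),
        detect_premature_beats(recording, exclude_spans=spans),
        tachy,
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return _empty_events()
    return pd.concat(parts, ignore_index=True).sort_values(
        "time_s", ignore_index=True
    )


def count_events(events: pd.DataFrame, span_h: float) -> ArrhythmiaCounts:
    """Per-class raw counts and counts normalised per 24 h."""
    if span_h <= 0:
        raise ConfigurationError("span_h must be positive")
    vc = events["event_class"].value_counts() if len(events) else {}
    raw = {c: int(vc.get(c, 0)) for c in EVENT_CLASSES}
    per24 = {c: raw[c] * 24.0 / span_h for c in EVENT_CLASSES}
    return ArrhythmiaCounts(raw=raw, per_24h=per24, span_h=float(span_h))


@dataclass
class ScoreResult:
    per_class: pd.DataFrame
    precision: float
    recall: float


def score_against_truth(
    events: pd.DataFrame, truth: TruthEventTable | pd.DataFrame, tol_s: float = 1.0
) -> ScoreResult:
    """Class-aware greedy one-to-one matching of detections to ground truth
    within +/- ``tol_s`` seconds; precision/recall per class and overall.

    Classes with no detections score precision 1 (nothing asserted wrongly);
    classes with no truth events score recall 1.
    """
    tdf = truth.df if isinstance(truth, TruthEventTable) else truth
    rows = []
    total_tp = total_fp = total_fn = 0
    for cls in EVENT_CLASSES:
        det = np.sort(events.loc[events["event_class"] == cls, "time_s"].to_numpy(float))
        tru = np.sort(tdf.loc[tdf["event_class"] == cls, "time_s"].to_numpy(float))
        i = j = tp = 0
        while i < det.size and j < tru.size:
            if abs(det[i] - tru[j]) <= tol_s:
                tp += 1
                i += 1
                j += 1
            elif det[i] < tru[j]:
                i += 1
            else:
                j += 1
        fp = det.size - tp
        fn = tru.size - tp
        total_tp += tp
        total_fp += fp
        total_fn += fn
        rows.append(
            {
                "event_class": cls,
                "n_truth": tru.size,
                "n_detected": det.size,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": tp / (tp + fp) if tp + fp else 1.0,
                "recall": tp / (tp + fn) if tp + fn else 1.0,
            }
        )
    return ScoreResult(
        per_class=pd.DataFrame(rows),
        precision=total_tp / (total_tp + total_fp) if total_tp + total_fp else 1.0,
        recall=total_tp / (total_tp + total_fn) if total_tp + total_fn else 1.0,
    )
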