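"""Interval-derived ECG parameters and the two windowing protocols.

Per-beat formulas (murine conventions):

* HR (beats/min) = 60 / (RR/1000), RR in ms
* QTc (ms)       = QT / sqrt(RR/100)   -- rate correction for mice, identity
  at RR = 100 ms

Two windowing protocols produce per-window interval tables:

* baseline: 10 min analysed every 30 min (600-s windows on an 1800-s grid
  anchored at recording start),
* drug challenge: contiguous, non-overlapping 10-min windows, those ending
  at or before the injection flagged as baseline.

Window means are computed over intervals (RR) and over per-beat annotations
(PR, QT); the window HR is derived from the window-mean RR (mean of the
intervals, then converted), and the window QTc from the window-mean QT and
RR.  Per-beat averaging of HR is available via ``hr_per_beat=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beats import Recording, to_rr_series
from .errors import ConfigurationError, DomainError, InsufficientDataError

INTERVAL_COLUMNS = [
    "t_start_s",
    "t_end_s",
    "mean_rr_ms",
    "hr_bpm",
    "mean_pr_ms",
    "mean_qt_ms",
    "mean_qtc_ms",
    "n_beats",
    "is_baseline",
]


def heart_rate(rr_ms):
    """Heart rate in beats/min from an RR interval in ms: 60/(RR/1000)."""
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(rr <= 0):
        raise DomainError("rr_ms must be positive")
    out = 60.0 / (rr / 1000.0)
    return float(out) if out.ndim == 0 else out

def qtc(qt_ms, rr_ms):
    """Rate-corrected QT in ms: QT / sqrt(RR/100) (identity at RR = 100 ms)."""
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise DomainError("qt_ms and rr_ms must be positive")
    out = qt / np.sqrt(rr / 100.0)
    return float(out) if out.ndim == 0 else out


def _window_table(
    recording: Recording,
    starts: np.ndarray,
    width_s: float,
    t_injection_s: float | None,
    hr_per_beat: bool,
) -> pd.DataFrame:
    rr = to_rr_series(recording)
    r_t = rr.r_times_s
    ev = recording.events
    is_r = (ev["kind"] == "R").to_numpy()
    rt_all = ev["time_s"].to_numpy(float)[is_r]
    pr_all = ev["pr_ms"].to_numpy(float)[is_r]
    qt_all = ev["qt_ms"].to_numpy(float)[is_r]

    rows = []
    for s in starts:
        e = s + width_s
        # intervals whose initial R lies in the window
        i0, i1 = np.searchsorted(r_t[:-1], [s, e])
        seg = rr.rr_ms[i0:i1]
        j0, j1 = np.searchsorted(rt_all, [s, e])
        pr_seg = pr_all[j0:j1]
        qt_seg = qt_all[j0:j1]
        if seg.size == 0:
            continue
        mean_rr = float(np.mean(seg))
        hr = float(np.mean(heart_rate(seg))) if hr_per_beat else heart_rate(mean_rr)
        mean_pr = float(np.nanmean(pr_seg)) if np.any(~np.isnan(pr_seg)) else np.nan
        mean_qt = float(np.nanmean(qt_seg)) if np.any(~np.isnan(qt_seg)) else np.nan
        mean_qtc = qtc(mean_qt, mean_rr) if np.isfinite(mean_qt) else np.nan
        rows.append(
            {
                "t_start_s": float(s),
                "t_end_s": float(e),
                "mean_rr_ms": mean_rr,
                "hr_bpm": hr,
                "mean_pr_ms": mean_pr,
                "mean_qt_ms": mean_qt,
                "mean_qtc_ms": mean_qtc,
                "n_beats": int(seg.size),
                "is_baseline": bool(t_injection_s is not None and e <= t_injection_s),
            }
        )
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def baseline_windows(recording: Recording, hr_per_beat: bool = False) -> pd.DataFrame:
    """Baseline protocol: 600-s windows starting every 1800 s from t = 0."""
    if recording.duration_s < 1800:
        raise InsufficientDataError("baseline protocol needs >= 30 min of recording")
    starts = np.arange(0.0, recording.duration_s - 600.0 + 1e-9, 1800.0)
    return _window_table(recording, starts, 600.0, None, hr_per_beat)


def drug_windows(
    recording: Recording, t_injection_s: float, hr_per_beat: bool = False
) -> pd.DataFrame:
    """Drug protocol: contiguous 600-s windows; pre-injection windows flagged
    baseline.  Requires >= 30 min of pre-injection recording."""
    if t_injection_s < 1800:
        raise ConfigurationError(
            "need >= 30 min of basal measurements before the injection"
        )
    if recording.duration_s < 1800:
        raise InsufficientDataError("drug protocol needs >= 30 min of recording")
    starts = np.arange(0.0, recording.duration_s - 600.0 + 1e-9, 600.0)
    return _window_table(recording, starts, 600.0, t_injection_s, hr_per_beat)


def percent_of_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``pct_baseline`` column: window HR as % of mean baseline HR."""
    if "is_baseline" not in table.columns or not table["is_baseline"].any():
        raise ConfigurationError("table has no baseline windows")
    base = float(table.loc[table["is_baseline"], "hr_bpm"].mean())
    out = table.copy()
    out["pct_baseline"] = out["hr_bpm"] / base * 100.0
    return out
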