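"""Time-domain heart-rate-variability analysis per 12-h light phase.

Sinus-beat screening excludes R-R intervals outside mean +/- 2 SD (bounds
inclusive, sample SD with n-1 denominator, computed once per segment in a
single pass).  On the retained ("normal", NN) intervals the four standard
time-domain statistics are computed:

* NN    -- mean of retained intervals (ms)
* SDNN  -- sample SD of retained intervals (ms), total variability
* RMSSD -- root mean square of successive differences (ms), short-term
  (vagally mediated) variability
* pNNx  -- percentage of successive differences with |diff| > x ms (strict
  inequality); x = 6 ms is the murine analogue of the human pNN50

Successive differences are taken only between retained intervals that were
adjacent in the original series: a difference spanning an excluded beat is
dropped rather than bridged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import Recording, segment_phases, to_rr_series
from .errors import InsufficientDataError


@dataclass
class HRVMetrics:
    phase: str
    nn_ms: float
    sdnn_ms: float
    rmssd_ms: float
    pnnx_pct: float
    x_ms: float
    n_retained: int
    n_excluded: int


def filter_sinus(rr_ms) -> tuple[np.ndarray, np.ndarray]:
    """Exclude intervals outside mean +/- 2 SD.

    Returns ``(retained, mask)`` where ``mask[i]`` is True for retained
    intervals.  Bounds are inclusive and computed once (single pass, not
    iterated); a constant series is therefore fully retained.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise InsufficientDataError("need >= 2 intervals to screen")
    mean = rr.mean()
    sd = rr.std(ddof=1)
    mask = (rr >= mean - 2.0 * sd) & (rr <= mean + 2.0 * sd)
    return rr[mask], mask


def hrv_metrics(rr_ms, x_ms: float = 6.0, retained_mask=None, phase: str = "all") -> HRVMetrics:
    """Time-domain HRV statistics of a (screened) interval sequence.

    ``rr_ms`` is the *original* segment when ``retained_mask`` is given (so
    that adjacency of retained intervals can be respected), or an already
    clean sequence otherwise.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if retained_mask is None:
        mask = np.ones(rr.size, dtype=bool)
    else:
        mask = np.asarray(retained_mask, dtype=bool)
        if mask.size != rr.size:
            raise ValueError("retained_mask length mismatch")
    kept = rr[mask]
    if kept.size < 2:
        raise InsufficientDataError("need >= 2 retained intervals")
    diff_ok = mask[1:] & mask[:-1]
    diffs = np.diff(rr)[diff_ok]
    if diffs.size < 1:
        raise InsufficientDataError("need >= 1 successive difference")
    return HRVMetrics(
        phase=phase,
        nn_ms=float(kept.mean()),
        sdnn_ms=float(kept.std(ddof=1)),
        rmssd_ms=float(np.sqrt(np.mean(diffs**2))),
        pnnx_pct=float(100.0 * np.mean(np.abs(diffs) > x_ms)),
        x_ms=float(x_ms),
        n_retained=int(kept.size),
        n_excluded=int(rr.size - kept.size),
    )


def hrv_day_night(recording: Recording, x_ms: float = 6.0) -> pd.DataFrame:
    """HRV metrics for the first complete 12-h day and night segments.

    Multi-day recordings are collapsed to the first complete 24 h (the first
    full window of each phase).  Returns one row per phase, night first,
    mirroring the standard night/day table layout.
    """
    windows = segment_phases(recording)
    full = [w for w in windows if w.duration_s >= 12 * 3600.0 - 1e-6]
    first: dict[str, object] = {}
    for w in full:
        first.setdefault(w.label, w)
    if "day" not in first or "night" not in first:
        raise InsufficientDataError(
            "recording must span at least one full 12-h day and night segment"
        )
    rr = to_rr_series(recording)
    starts = rr.r_times_s[:-1]  # interval assigned to the phase of its initial R
    rows = []
    for label in ("night", "day"):
        w = first[label]
        seg = rr.rr_ms[(starts >= w.t_start_s) & (starts < w.t_end_s)]
        if seg.size < 2:
            raise InsufficientDataError(f"too few beats in {label} segment")
        _, mask = filter_sinus(seg)
        rows.append(hrv_metrics(seg, x_ms=x_ms, retained_mask=mask, phase=label))
    return pd.DataFrame([r.__dict__ for r in rows])
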