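"""Annotated telemetry recordings.

A recording is an ordered stream of beat annotations: one event per detected
P wave or R peak, each carrying a timestamp (seconds from recording start),
an event kind (``P`` or ``R``), a P-wave morphology tag (``sinus``/``ectopic``
for P events, ``na`` for R events) and, on R rows, optional per-beat PR and QT
intervals in milliseconds.  This event-stream representation (rather than one
row per beat) is deliberate: conduction defects such as AV block, where a P
wave has no following QRS, are representable.

Events are stored internally as a :class:`pandas.DataFrame` for speed; the
:class:`BeatEvent` dataclass is the per-row view used in small-scale
construction and iteration.

The on-disk format is a plain CSV with ``# key=value`` comment headers for the
recording metadata followed by ``time_s,kind,morph,pr_ms,qt_ms`` rows (UTF-8,
'.' decimal separator, empty fields for absent optionals).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InsufficientDataError

KINDS = ("P", "R")
MORPHS = ("sinus", "ectopic", "na")
GENOTYPES = ("wt", "het", "ko")

EVENT_COLUMNS = ["time_s", "kind", "morph", "pr_ms", "qt_ms"]

_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})$")


def parse_clock(clock: str) -> int:
    """Parse an ``hh:mm`` clock string into minutes past midnight."""
    m = _CLOCK_RE.match(str(clock).strip())
    if not m:
        raise ConfigurationError(f"bad clock time {clock!r}, expected hh:mm")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh >= 24 or mm >= 60:
        raise ConfigurationError(f"bad clock time {clock!r}")
    return hh * 60 + mm


@dataclass
class BeatEvent:
    """A single annotated event (P wave or R peak)."""

    time_s: float
    kind: str
    morph: str = "na"
    pr_ms: float | None = None
    qt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise FormatError(f"unknown event kind {self.kind!r}")
        if self.morph not in MORPHS:
            raise FormatError(f"unknown morphology tag {self.morph!r}")
        if self.time_s < 0:
            raise FormatError(f"negative event time {self.time_s}")
        for name in ("pr_ms", "qt_ms"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise FormatError(f"{name} must be positive, got {v}")


@dataclass
class Recording:
    """A time-ordered annotated telemetry recording with its metadata.

    ``events`` is a DataFrame with columns ``time_s, kind, morph, pr_ms,
    qt_ms`` sorted by time (P before R on ties).  ``lights_on_clock`` and
    ``t0_clock`` are ``hh:mm`` wall-clock strings anchoring the recording in
    the 12 h light / 12 h dark husbandry cycle.
    """

    events: pd.DataFrame
    animal_id: str = "unknown"
    genotype: str = "wt"
    lights_on_clock: str | None = None
    t0_clock: str | None = None
    duration_s: float = 0.0

    @classmethod
    def from_events(cls, events: Sequence[BeatEvent], **meta) -> "Recording":
        df = pd.DataFrame(
            [(e.time_s, e.kind, e.morph, e.pr_ms, e.qt_ms) for e in events],
            columns=EVENT_COLUMNS,
        )
        for col in ("time_s", "pr_ms", "qt_ms"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        rec = cls(events=df, **meta)
        rec.sort_events()
        rec.validate()
        return rec

    @property
    def n_events(self) -> int:
        return len(self.events)

    def iter_events(self) -> Iterator[BeatEvent]:
        for row in self.events.itertuples(index=False):
            yield BeatEvent(
                time_s=float(row.time_s),
                kind=row.kind,
                morph=row.morph,
                pr_ms=None if pd.isna(row.pr_ms) else float(row.pr_ms),
                qt_ms=None if pd.isna(row.qt_ms) else float(row.qt_ms),
            )

    def sort_events(self) -> None:
        """Sort by time; P ordered before R on exact ties (physiological order)."""
        kind_rank = (self.events["kind"] == "R").to_numpy()
        order = np.lexsort((kind_rank, self.events["time_s"].to_numpy()))
        self.events = self.events.iloc[order].reset_index(drop=True)

    def validate(self) -> None:
        df = self.events
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"events table missing columns {missing}")
        if self.genotype not in GENOTYPES:
            raise FormatError(f"unknown genotype {self.genotype!r}")
        if len(df) == 0:
            return
        t = df["time_s"].to_numpy(float)
        if np.any(t < 0):
            raise FormatError("negative event time")
        if np.any(np.diff(t) < 0):
            raise FormatError("event times are not sorted")
        if np.any(t >= self.duration_s):
            raise FormatError("event time at or beyond duration_s")
        bad_kind = ~df["kind"].isin(KINDS)
        if bad_kind.any():
            raise FormatError(
                f"unknown kind {df.loc[bad_kind, 'kind'].iloc[0]!r}"
            )
        bad_morph = ~df["morph"].isin(MORPHS)
        if bad_morph.any():
            raise FormatError(
                f"unknown morph {df.loc[bad_morph, 'morph'].iloc[0]!r}"
            )
        for col in ("pr_ms", "qt_ms"):
            v = df[col].to_numpy(float)
            if np.any(v[~np.isnan(v)] <= 0):
                raise FormatError(f"non-positive {col}")

    def r_times(self) -> np.ndarray:
        """Times (s) of R events only."""
        mask = self.events["kind"].to_numpy() == "R"
        return self.events["time_s"].to_numpy(float)[mask]

    def p_table(self) -> pd.DataFrame:
        """Sub-table of P events (time and morphology)."""
        mask = self.events["kind"] == "P"
        return self.events.loc[mask, ["time_s", "morph"]].reset_index(drop=True)


@dataclass
class RRSeries:
    """Ordered R-peak times (s) and the successive inter-beat intervals (ms)."""

    r_times_s: np.ndarray
    rr_ms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r_times_s = np.asarray(self.r_times_s, float)
        if self.r_times_s.size < 2:
            raise InsufficientDataError("need at least 2 R events for an RR series")
        self.rr_ms = np.diff(self.r_times_s) * 1000.0
        if np.any(self.rr_ms <= 0):
            raise FormatError("non-positive RR interval (duplicate or unsorted R times)")

    def __len__(self) -> int:
        return len(self.rr_ms)


@dataclass(frozen=True)
class PhaseWindow:
    """A half-open light-phase window ``[t_start_s, t_end_s)``."""

    label: str  # "day" (lights on) or "night" (lights off)
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if self.label not in ("day", "night"):
            raise ConfigurationError(f"bad phase label {self.label!r}")
        if not self.t_end_s > self.t_start_s:
            raise ConfigurationError("empty phase window")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def to_rr_series(recording: Recording) -> RRSeries:
    """Derive the RR-interval series from the R events of a recording.

    P events are ignored; at least two R events are required.
    """
    rt = recording.r_times()
    if rt.size < 2:
        raise InsufficientDataError(
            f"need at least 2 R events, found {rt.size}"
        )
    return RRSeries(r_times_s=rt)


def segment_phases(recording: Recording) -> list[PhaseWindow]:
    """Tile ``[0, duration_s)`` with alternating 12-h day/night windows.

    The phase grid is anchored on the recording's wall-clock metadata
    (``lights_on_clock`` marks the start of the 12-h light = "day" phase,
    under the standard 12 h light / 12 h dark cycle); the first and last
    windows are clipped to the recording extent.
    """
    if recording.lights_on_clock is None or recording.t0_clock is None:
        raise ConfigurationError("lights_on_clock and t0_clock metadata required")
    return build_phase_windows(
        recording.lights_on_clock, recording.t0_clock, recording.duration_s
    )


def build_phase_windows(
    lights_on_clock: str, t0_clock: str, duration_s: float
) -> list[PhaseWindow]:
    """Phase tiling from raw clock metadata (see :func:`segment_phases`)."""
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    half_day = 12 * 3600.0
    offset_min = (parse_clock(t0_clock) - parse_clock(lights_on_clock)) % 1440
    offset_s = offset_min * 60.0
    if offset_s < half_day:
        label, into = "day", offset_s
    else:
        label, into = "night", offset_s - half_day

    windows: list[PhaseWindow] = []
    t = 0.0
    remaining_first = half_day - into
    t_end = min(remaining_first, duration_s)
    while t < duration_s:
        windows.append(PhaseWindow(label, t, t_end))
        label = "night" if label == "day" else "day"
        t = t_end
        t_end = min(t + half_day, duration_s)
    return windows


def phase_of_times(times_s: np.ndarray, windows: Sequence[PhaseWindow]) -> np.ndarray:
    """Vectorized phase lookup: boolean array, True where the time falls in a day window."""
    starts = np.array([w.t_start_s for w in windows])
    labels = np.array([w.label == "day" for w in windows])
    idx = np.clip(np.searchsorted(starts, times_s, side="right") - 1, 0, len(windows) - 1)
    return labels[idx]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("animal_id", "genotype", "lights_on_clock", "t0_clock", "duration_s")


def write_beat_csv(recording: Recording, path) -> None:
    """Write a recording in the beat-event CSV dialect (round-trips with
    :func:`read_beat_csv`; times to 1e-4 s, intervals to 1e-2 ms)."""
    recording.validate()
    buf = io.StringIO()
    meta = {
        "animal_id": recording.animal_id,
        "genotype": recording.genotype,
        "lights_on_clock": recording.lights_on_clock,
        "t0_clock": recording.t0_clock,
        "duration_s": repr(float(recording.duration_s)),
    }
    for key, value in meta.items():
        if value is not None:
            buf.write(f"# {key}={value}\n")
    df = recording.events.copy()
    df["time_s"] = df["time_s"].map(lambda v: f"{v:.4f}")
    for col in ("pr_ms", "qt_ms"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_beat_csv(path) -> Recording:
    """Parse a beat-event CSV file into a :class:`Recording`.

    Raises :class:`FormatError` naming the offending line for malformed rows,
    unknown kinds/morphology tags or non-monotone timestamps.
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    try:
        df = pd.read_csv(
            io.StringIO("".join(lines[body_start:])),
            dtype={"kind": str, "morph": str},
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unparsable CSV body: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[EVENT_COLUMNS]
    for col in ("time_s", "pr_ms", "qt_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        # pr/qt may be legitimately empty; time may not
    header_lines = body_start + 1  # comments + column header

    def _lineno(row_idx: int) -> int:
        return header_lines + row_idx + 1

    if df["time_s"].isna().any():
        bad = int(df.index[df["time_s"].isna()][0])
        raise FormatError(f"{path}:{_lineno(bad)}: bad or missing time_s")
    bad_kind = ~df["kind"].isin(KINDS)
    if bad_kind.any():
        bad = int(df.index[bad_kind][0])
        raise FormatError(
            f"{path}:{_lineno(bad)}: unknown kind {df['kind'].iloc[bad]!r}"
        )
    bad_morph = ~df["morph"].isin(MORPHS)
    if bad_morph.any():
        bad = int(df.index[bad_morph][0])
        raise FormatError(
            f"{path}:{_lineno(bad)}: unknown morph {df['morph'].iloc[bad]!r}"
        )
    dt = np.diff(df["time_s"].to_numpy(float))
    if np.any(dt < 0):
        bad = int(np.argmax(dt < 0)) + 1
        raise FormatError(f"{path}:{_lineno(bad)}: non-monotone time_s")

    duration = float(meta.get("duration_s", 0.0))
    rec = Recording(
        events=df.reset_index(drop=True),
        animal_id=meta.get("animal_id", "unknown"),
        genotype=meta.get("genotype", "wt"),
        lights_on_clock=meta.get("lights_on_clock"),
        t0_clock=meta.get("t0_clock"),
        duration_s=duration,
    )
    rec.validate()
    return rec
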