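"""Shared fixtures: small hand-constructed recordings and beat builders."""

from __future__ import annotations

import numpy as np
import pytest

from cardiotel.beats import Recording
from cardiotel.simulate import BeatFrame


def make_frame(rr_ms, t_first_s: float = 0.2, pr_ms: float = 35.0,
               qt_ms: float = 28.0) -> BeatFrame:
    """Beat buffer with the given RR intervals, all-sinus morphology and
    constant PR/QT annotations."""
    rr = np.asarray(rr_ms, dtype=float)
    n = rr.size + 1
    return BeatFrame(
        t_first_s=t_first_s,
        rr_ms=rr.copy(),
        morph=np.full(n, "sinus", dtype=object),
        pr_ms=np.full(n, float(pr_ms)),
        qt_ms=np.full(n, float(qt_ms)),
    )


def make_recording(rr_ms, duration_s: float | None = None, **meta) -> Recording:
    """Recording with the given RR intervals (P + R events per beat)."""
    frame = make_frame(rr_ms)
    return frame.to_recording(duration_s=duration_s, **meta)


@pytest.fixture
def constant_recording() -> Recording:
    """1 h of perfectly regular beats at RR = 120 ms."""
    n = int(3599.0 / 0.120)
    return make_recording([120.0] * (n - 1), duration_s=3600.0,
                          lights_on_clock="07:00", t0_clock="07:00")
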