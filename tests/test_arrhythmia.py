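"""Rule-based arrhythmia detection on constructed beat streams."""

import numpy as np
import pandas as pd
import pytest

from cardiotel.arrhythmia import (
    count_events,
    detect_arrhythmias,
    detect_av_blocks,
    detect_escape_beats,
    detect_premature_beats,
    detect_tachy_brady,
    local_normal_pp,
    score_against_truth,
)
from cardiotel.errors import ConfigurationError
from cardiotel.simulate import (
    inject_av_block,
    inject_escape_beat,
    inject_tachy_brady_episode,
)

from conftest import make_frame


def jittered_rr(n, rr=100.0, amp=1.0):
    """Deterministic small alternating jitter (gives the detector a non-zero
    variability estimate without randomness)."""
    return rr + amp * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)


class TestLocalNormalPP:
    def test_constant_pp(self):
        rec = make_frame([100.0] * 60).to_recording()
        assert local_normal_pp(rec, 30) == pytest.approx(100.0, abs=0.5)

    def test_median_robust_to_pause(self):
        frame = make_frame([100.0] * 60)
        frame.rr_ms[29] = 250.0
        rec = frame.to_recording()
        assert local_normal_pp(rec, 35) == pytest.approx(100.0, abs=0.5)

    def test_fallback_to_segment_median(self):
        rec = make_frame([100.0] * 5).to_recording()
        assert local_normal_pp(rec, 2) == pytest.approx(100.0, abs=0.5)


class TestEscapeBeats:
    def _with_escape(self, factor, variant):
        frame = make_frame([100.0] * 80)
        inject_escape_beat(frame, 40, factor, variant)
        return frame.to_recording()

    def test_long_escape(self):
        events = detect_escape_beats(self._with_escape(2.5, "long"))
        assert list(events["event_class"]) == ["escape_long"]
        assert events["detail"].iloc[0] == pytest.approx(250.0)

    def test_short_escape(self):
        events = detect_escape_beats(self._with_escape(1.8, "short"))
        assert list(events["event_class"]) == ["escape_short"]

    def test_boundary_pause_exactly_two_pp_is_short(self):
        """Strict > for the long class: a 2.0x pause classifies short."""
        frame = make_frame([100.0] * 80)
        frame.rr_ms[40] = 200.0
        frame.morph[41] = "ectopic"
        events = detect_escape_beats(frame.to_recording())
        assert list(events["event_class"]) == ["escape_short"]

    def test_interval_only_mode(self):
        frame = make_frame(jittered_rr(80))
        frame.rr_ms[40] = 250.0  # pause without a morphology tag
        events = detect_escape_beats(frame.to_recording(), mode="interval")
        assert list(events["event_class"]) == ["escape_long"]

    def test_no_candidates_no_events(self):
        events = detect_escape_beats(make_frame([100.0] * 50).to_recording())
        assert len(events) == 0


class TestAvBlocks:
    def test_two_p_one_qrs(self):
        frame = make_frame([100.0] * 40)
        inject_av_block(frame, 20, 1)
        events = detect_av_blocks(frame.to_recording())
        assert len(events) == 1
        assert events["detail"].iloc[0] == 2.0

    def test_three_p_single_event(self):
        frame = make_frame([100.0] * 40)
        inject_av_block(frame, 20, 2)
        events = detect_av_blocks(frame.to_recording())
        assert len(events) == 1
        assert events["detail"].iloc[0] == 3.0

    def test_regular_conduction_clean(self):
        assert len(detect_av_blocks(make_frame([100.0] * 40).to_recording())) == 0


class TestPrematureBeats:
    @pytest.mark.parametrize("rr,detected", [(60.0, True), (80.0, False), (74.9, True)])
    def test_threshold(self, rr, detected):
        frame = make_frame([100.0] * 60)
        frame.rr_ms[30] = rr
        events = detect_premature_beats(frame.to_recording())
        assert (len(events) == 1) is detected

    def test_exclusion_inside_episodes(self):
        frame = make_frame([100.0] * 60)
        frame.rr_ms[30] = 60.0
        t_beat = frame.r_times_s()[31]
        events = detect_premature_beats(
            frame.to_recording(), exclude_spans=[(t_beat - 1, t_beat + 1)]
        )
        assert len(events) == 0


class TestTachyBrady:
    def _with_episode(self, n=2400, gap_s=60.0):
        frame = make_frame(jittered_rr(n))
        rng = np.random.default_rng(0)
        idx2 = None
        inject_tachy_brady_episode(
            frame, 400, high_hr_bpm=750.0, low_hr_bpm=400.0, span_s=10.0,
            baseline_hr_bpm=600.0, rng=rng,
        )
        if gap_s is not None:
            idx2 = 400 + int(gap_s / 0.1) + 200
            inject_tachy_brady_episode(
                frame, idx2, high_hr_bpm=750.0, low_hr_bpm=400.0, span_s=10.0,
                baseline_hr_bpm=600.0, rng=rng,
            )
        return frame

    def test_single_scripted_swing_detected(self):
        frame = make_frame(jittered_rr(1200))
        inject_tachy_brady_episode(
            frame, 400, high_hr_bpm=750.0, low_hr_bpm=400.0, span_s=10.0,
            baseline_hr_bpm=600.0, rng=np.random.default_rng(0),
        )
        events = detect_tachy_brady(frame.to_recording())
        assert len(events) == 1

    def test_monotone_tachycardia_not_flagged(self):
        frame = make_frame(jittered_rr(1200))
        frame.rr_ms[400:460] = 80.0  # tachycardia without the brady limb
        assert len(detect_tachy_brady(frame.to_recording())) == 0

    def test_two_swings_give_two_events(self):
        events = detect_tachy_brady(self._with_episode(gap_s=60.0).to_recording())
        assert len(events) == 2

    def test_single_extreme_beats_debounced(self):
        frame = make_frame(jittered_rr(1200))
        frame.rr_ms[400] = 70.0   # lone fast beat
        frame.rr_ms[420] = 160.0  # lone slow beat
        assert len(detect_tachy_brady(frame.to_recording())) == 0


class TestCountsAndScoring:
    def _events(self, times, cls="escape_short"):
        return pd.DataFrame(
            {"time_s": times, "event_class": cls, "detail": np.nan}
        )

    def test_normalisation(self):
        counts = count_events(self._events(np.arange(10.0)), span_h=12.0)
        assert counts.raw["escape_short"] == 10
        assert counts.per_24h["escape_short"] == pytest.approx(20.0)

    def test_empty_and_identity_span(self):
        counts = count_events(self._events([]), span_h=24.0)
        assert all(v == 0 for v in counts.raw.values())
        counts = count_events(self._events([1.0, 2.0]), span_h=24.0)
        assert counts.per_24h["escape_short"] == counts.raw["escape_short"]

    def test_counts_conserve_events(self):
        ev = pd.concat(
            [self._events([1.0, 2.0]), self._events([3.0], cls="av_block")],
            ignore_index=True,
        )
        counts = count_events(ev, span_h=24.0)
        assert sum(counts.raw.values()) == len(ev)

    def test_perfect_detection(self):
        truth = self._events(np.arange(9.0))
        score = score_against_truth(truth, truth)
        assert score.precision == 1.0 and score.recall == 1.0

    def test_empty_detection(self):
        score = score_against_truth(self._events([]), self._events([1.0, 2.0]))
        assert score.recall == 0.0

    def test_one_spurious_event(self):
        truth = self._events(np.arange(0.0, 90.0, 10.0))  # 9 events
        det = self._events(list(np.arange(0.0, 90.0, 10.0)) + [1000.0])
        score = score_against_truth(det, truth)
        assert score.precision == pytest.approx(0.9)
        assert score.recall == 1.0

    def test_class_aware_matching(self):
        truth = self._events([10.0], cls="av_block")
        det = self._events([10.0], cls="escape_long")
        score = score_against_truth(det, truth)
        assert score.precision == 0.0 and score.recall == 0.0


def test_detection_invariant_under_time_shift():
    frame = make_frame(jittered_rr(2000))
    inject_escape_beat(frame, 300, 2.5, "long")
    inject_av_block(frame, 600, 1)
    frame.rr_ms[900] = 60.0
    rec = frame.to_recording()
    shifted = make_frame(jittered_rr(2000))
    inject_escape_beat(shifted, 300, 2.5, "long")
    inject_av_block(shifted, 600, 1)
    shifted.rr_ms[900] = 60.0
    shifted.t_first_s += 500.0
    rec2 = shifted.to_recording()
    ev1 = detect_arrhythmias(rec)
    ev2 = detect_arrhythmias(rec2)
    assert list(ev1["event_class"]) == list(ev2["event_class"])
    np.testing.assert_allclose(ev2["time_s"], ev1["time_s"] + 500.0, atol=1e-9)


def test_unknown_escape_mode_rejected():
    with pytest.raises(ConfigurationError):
        detect_escape_beats(make_frame([100.0] * 50).to_recording(), mode="bogus")
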