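"""Synthetic telemetry generator: degenerate cases, determinism, injectors,
drug transients and the calibration of the RR noise process."""

import numpy as np
import pytest
from scipy import stats as sps

from cardiotel.beats import read_beat_csv, to_rr_series, write_beat_csv
from cardiotel.errors import ConfigurationError, DomainError, PlacementError
from cardiotel.simulate import (
    DrugEvent,
    ScenarioConfig,
    drug_hr_factor,
    generate_recording,
    inject_av_block,
    inject_escape_beat,
    inject_premature_beat,
    inject_tachy_brady_episode,
    load_scenario,
    packaged_scenarios,
)

from conftest import make_frame


def quiet_config(**kw) -> ScenarioConfig:
    base = dict(
        mu_rr_day_ms=120.0,
        mu_rr_night_ms=120.0,
        sigma_white_ms=0.0,
        sigma_slow_ms=0.0,
        pr_sd_ms=0.0,
        qt_sd_ms=0.0,
        duration_h=1.0,
        seed=7,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestGenerateRecording:
    def test_zero_noise_constant_rr(self):
        rec, truth = generate_recording(quiet_config())
        rr = to_rr_series(rec).rr_ms
        np.testing.assert_allclose(rr, 120.0, atol=1e-9)
        assert len(truth) == 0

    def test_seed_determinism(self):
        cfg = load_scenario("wt_baseline", seed=3, duration_h=0.5)
        r1, t1 = generate_recording(cfg)
        r2, t2 = generate_recording(load_scenario("wt_baseline", seed=3, duration_h=0.5))
        assert r1.events.equals(r2.events)
        assert t1.df.equals(t2.df)

    def test_different_seed_differs(self):
        cfg1 = load_scenario("wt_baseline", seed=1, duration_h=0.5)
        cfg2 = load_scenario("wt_baseline", seed=2, duration_h=0.5)
        assert not generate_recording(cfg1)[0].events.equals(
            generate_recording(cfg2)[0].events
        )

    def test_truth_counts_poisson(self):
        """Injected counts across seeds follow the configured Poisson law."""
        rate = 48.0  # per 24 h -> mean 2 per 1-h recording
        counts = []
        for seed in range(200):
            cfg = quiet_config(
                mu_rr_day_ms=400.0, mu_rr_night_ms=400.0, seed=seed,
                event_rates_per_24h={"escape_short": rate},
            )
            _, truth = generate_recording(cfg)
            counts.append(truth.counts()["escape_short"])
        counts = np.asarray(counts)
        mean = rate / 24.0
        assert counts.mean() == pytest.approx(mean, abs=3 * np.sqrt(mean / 200))
        # chi-square GOF against Poisson(mean), pooled tails
        kmax = int(sps.poisson.ppf(0.999, mean)) + 1
        obs = np.bincount(counts, minlength=kmax + 1)[: kmax + 1].astype(float)
        obs[kmax] += (counts > kmax).sum()
        exp = sps.poisson.pmf(np.arange(kmax + 1), mean) * len(counts)
        exp[kmax] = len(counts) - exp[:kmax].sum()
        keep = exp > 1.0
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_generated_recording_round_trips(self, tmp_path):
        cfg = load_scenario("mixed_events", seed=5, duration_h=0.4)
        rec, _ = generate_recording(cfg)
        path = tmp_path / "gen.csv"
        write_beat_csv(rec, path)
        back = read_beat_csv(path)
        assert back.n_events == rec.n_events
        np.testing.assert_allclose(
            back.events["time_s"], rec.events["time_s"], atol=1e-4
        )

    def test_noise_process_calibration(self):
        """Clean-process SDNN and RMSSD match their closed forms.

        SDNN -> sqrt(sigma_white^2 + sigma_slow^2/(1-phi^2)) and
        RMSSD -> sigma_white*sqrt(2) within 10% at ~1e5 beats.
        """
        sw, si, phi = 4.0, 1.0, 0.998
        cfg = quiet_config(
            mu_rr_day_ms=110.0, mu_rr_night_ms=110.0,
            sigma_white_ms=sw, sigma_slow_ms=si, ar_phi=phi,
            duration_h=3.2, seed=11,
        )
        rr = to_rr_series(generate_recording(cfg)[0]).rr_ms
        assert rr.size > 1e5
        sdnn_expect = np.sqrt(sw**2 + si**2 / (1 - phi**2))
        assert rr.std(ddof=1) == pytest.approx(sdnn_expect, rel=0.10)
        assert np.sqrt(np.mean(np.diff(rr) ** 2)) == pytest.approx(sw * np.sqrt(2), rel=0.10)
        # SE of the mean must account for the AR(1) autocorrelation
        stat = si / np.sqrt(1 - phi**2)
        se = np.sqrt((sw**2 + stat**2 * (1 + phi) / (1 - phi)) / rr.size)
        assert rr.mean() == pytest.approx(110.0, abs=3 * se)

    def test_phase_means_follow_circadian_profile(self):
        cfg = quiet_config(
            mu_rr_day_ms=137.0, mu_rr_night_ms=112.0,
            sigma_white_ms=1.0, duration_h=24.0, seed=2,
        )
        rec, _ = generate_recording(cfg)
        rr = to_rr_series(rec)
        day = rr.r_times_s[:-1] < 43200.0
        assert rr.rr_ms[day].mean() == pytest.approx(137.0, abs=0.1)
        assert rr.rr_ms[~day].mean() == pytest.approx(112.0, abs=0.1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_recording(quiet_config(ar_phi=1.5))
        with pytest.raises(ConfigurationError):
            ScenarioConfig(mu_rr_day_ms=-1.0).validate()

    def test_packaged_scenarios_present(self):
        names = packaged_scenarios()
        for required in ("wt_baseline", "ko_baseline", "ko_carbachol", "mixed_events"):
            assert required in names
        for name in names:
            load_scenario(name).validate()


class TestInjectors:
    def test_escape_long(self):
        frame = make_frame([100.0] * 60)
        row = inject_escape_beat(frame, 30, 2.5, "long")
        assert frame.rr_ms[30] == pytest.approx(250.0)
        assert frame.morph[31] == "ectopic"
        assert row["event_class"] == "escape_long"

    def test_escape_short(self):
        frame = make_frame([100.0] * 60)
        row = inject_escape_beat(frame, 30, 1.8, "short")
        assert frame.rr_ms[30] == pytest.approx(180.0)
        assert row["event_class"] == "escape_short"

    def test_escape_factor_one_rejected(self):
        with pytest.raises(DomainError):
            inject_escape_beat(make_frame([100.0] * 60), 30, 1.0, "short")

    @pytest.mark.parametrize("extra_p,expected", [(1, 2), (2, 3)])
    def test_av_block_p_multiplicity(self, extra_p, expected):
        frame = make_frame([100.0] * 20)
        inject_av_block(frame, 10, extra_p)
        rec = frame.to_recording()
        t = rec.events["time_s"].to_numpy()
        is_r = (rec.events["kind"] == "R").to_numpy()
        r_t = t[is_r]
        in_gap = (~is_r) & (t > r_t[10]) & (t <= r_t[11])
        assert in_gap.sum() == expected

    def test_av_block_zero_rejected(self):
        with pytest.raises(DomainError):
            inject_av_block(make_frame([100.0] * 20), 10, 0)

    def test_premature_with_compensation(self):
        frame = make_frame([100.0] * 60)
        inject_premature_beat(frame, 30, 0.5)
        assert frame.rr_ms[30] == pytest.approx(50.0)
        assert frame.rr_ms[31] == pytest.approx(150.0)
        # downstream beat times preserved
        assert frame.r_times_s()[-1] == pytest.approx(0.2 + 6.0)

    def test_premature_factor_074(self):
        frame = make_frame([100.0] * 60)
        inject_premature_beat(frame, 30, 0.74)
        assert frame.rr_ms[30] == pytest.approx(74.0)

    def test_premature_factor_too_large_rejected(self):
        with pytest.raises(DomainError):
            inject_premature_beat(make_frame([100.0] * 60), 30, 0.8)

    def test_tachy_brady_ramp(self):
        frame = make_frame([100.0] * 400)  # baseline 600 bpm
        rng = np.random.default_rng(0)
        row, delta = inject_tachy_brady_episode(
            frame, 100, high_hr_bpm=750.0, low_hr_bpm=400.0, span_s=10.0,
            baseline_hr_bpm=600.0, rng=rng,
        )
        assert row["event_class"] == "tachy_brady"
        rr_high = 60000.0 / 750.0
        rr_low = 60000.0 / 400.0
        n_high = int(round(5000.0 / rr_high))
        np.testing.assert_allclose(frame.rr_ms[100 : 100 + n_high], rr_high)
        assert frame.rr_ms[100 + n_high] == pytest.approx(rr_low)
        # truth anchors on bradycardia onset
        assert row["beat_index"] == 100 + n_high

    def test_tachy_requires_bracketing_rates(self):
        frame = make_frame([100.0] * 400)
        with pytest.raises(DomainError):
            inject_tachy_brady_episode(
                frame, 100, high_hr_bpm=500.0, low_hr_bpm=400.0, span_s=10.0,
                baseline_hr_bpm=600.0, rng=np.random.default_rng(0),
            )

    def test_tachy_degenerate_span(self):
        frame = make_frame([100.0] * 400)
        with pytest.raises(PlacementError):
            inject_tachy_brady_episode(
                frame, 100, high_hr_bpm=700.0, low_hr_bpm=60.0, span_s=2.0,
                baseline_hr_bpm=600.0, rng=np.random.default_rng(0),
            )


class TestDrugTransient:
    entry = DrugEvent(
        drug="carbachol", t_injection_s=1000.0, target_factor=0.5,
        tau_onset_s=60.0, plateau_s=1200.0, tau_recovery_s=120.0,
    )

    def test_identity_before_injection(self):
        assert drug_hr_factor(999.0, self.entry) == 1.0

    def test_plateau_value(self):
        assert drug_hr_factor(1600.0, self.entry) == pytest.approx(0.5, abs=1e-4)

    def test_recovery_within_one_percent_after_five_tau(self):
        t = 1000.0 + 1200.0 + 5 * 120.0
        assert drug_hr_factor(t, self.entry) == pytest.approx(1.0, abs=0.01)

    def test_target_hr_resolution(self):
        entry = DrugEvent(drug="carbachol", t_injection_s=0.0, target_hr_bpm=300.0)
        assert entry.resolve_factor(600.0) == pytest.approx(0.5)
        with pytest.raises(ConfigurationError):
            entry.resolve_factor(None)
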