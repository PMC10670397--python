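"""Simulator contracts: determinism, state mix, parameter recovery."""

from dataclasses import replace

import numpy as np
import pytest

from neosleep import SimConfig, read_recording, simulate_recording
from neosleep.config import EPOCH_S, StateParams
from neosleep.synthetic import (
    Hypnogram,
    generate_ecg_waveform,
    generate_hypnogram,
    generate_motion,
    generate_respiration,
    generate_rpeaks,
    simulate_cohort,
)


def qs_only(n: int) -> Hypnogram:
    return Hypnogram(labels=tuple(["QS"] * n))


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(state_fractions={"AS": 0.5, "QS": 0.2, "CTW": 0.2})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            StateParams(
                mean_rr=400, sd_rr=-1, decel_rate=0, decel_depth=0,
                breath_rate=50, breath_rate_jitter=0, breath_amp=1,
                breath_amp_cv=0, motion_burst_rate=0, motion_burst_amp=0,
            )

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            SimConfig(duration_epochs=0)


class TestHypnogram:
    def test_state_mix_close_to_configured(self):
        for seed in (0, 1, 2):
            h = generate_hypnogram(SimConfig(seed=seed, duration_epochs=1000))
            assert h.fractions()["AS"] == pytest.approx(0.72, abs=0.05)

    def test_single_epoch_duration(self):
        assert len(generate_hypnogram(SimConfig(seed=0, duration_epochs=1))) == 1

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42, duration_epochs=200)
        assert generate_hypnogram(cfg).labels == generate_hypnogram(cfg).labels

    def test_bout_lengths_geometric_means(self):
        import itertools

        h = generate_hypnogram(SimConfig(seed=7, duration_epochs=4000))
        bouts = {s: [] for s in ("AS", "QS", "CTW")}
        for k, grp in itertools.groupby(h.labels):
            bouts[k].append(len(list(grp)))
        # geometric(mean L): SE of the mean is ~L/sqrt(n_bouts)
        for s, target in (("AS", 20.0), ("QS", 10.0), ("CTW", 5.0)):
            m = np.mean(bouts[s])
            se = target / np.sqrt(len(bouts[s]))
            assert abs(m - target) < 3 * se


class TestRPeaks:
    def test_mean_rr_recovered_qs(self):
        cfg = SimConfig(seed=3)
        qs = replace(cfg.state_params["QS"], decel_rate=0.0)
        cfg = replace(cfg, state_params={**cfg.state_params, "QS": qs})
        rp = generate_rpeaks(qs_only(100), cfg)
        rr = np.diff(rp) * 1000
        se = rr.std() / np.sqrt(rr.size)
        assert abs(rr.mean() - 430.0) < max(3 * se, 5.0)

    def test_zero_noise_gives_constant_intervals(self):
        cfg = SimConfig(seed=0)
        qs = replace(cfg.state_params["QS"], sd_rr=0.0, decel_rate=0.0)
        cfg = replace(cfg, state_params={**cfg.state_params, "QS": qs})
        rr = np.diff(generate_rpeaks(qs_only(10), cfg)) * 1000
        assert np.allclose(rr, 430.0, atol=1e-9)

    def test_decelerations_prolong_runs(self):
        cfg = SimConfig(seed=1)
        qs = replace(
            cfg.state_params["QS"], sd_rr=0.0, decel_rate=2.0, decel_depth=0.3
        )
        cfg = replace(cfg, state_params={**cfg.state_params, "QS": qs})
        rr = np.diff(generate_rpeaks(qs_only(50), cfg)) * 1000
        # scan for samples at >= (1 + depth) x baseline
        assert np.any(rr >= 430.0 * 1.3 - 1e-6)

    def test_strictly_increasing(self):
        rp = generate_rpeaks(qs_only(20), SimConfig(seed=5))
        assert np.all(np.diff(rp) > 0)


class TestRespiration:
    def test_zero_jitter_identical_periods(self):
        cfg = SimConfig(seed=2)
        qs = replace(cfg.state_params["QS"], breath_rate_jitter=0.0, breath_rate=60.0)
        cfg = replace(cfg, state_params={**cfg.state_params, "QS": qs})
        x = generate_respiration(qs_only(1), cfg)
        # 60 breaths/min -> ~30 peaks in 30 s
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(x, prominence=0.2 * x.std())
        assert abs(len(peaks) - 30) <= 1
        # peak indices are quantized to the 16-Hz grid: +/- 1 sample each
        periods = np.diff(peaks) / cfg.resp_rate
        assert np.allclose(periods, np.median(periods), atol=1.5 / cfg.resp_rate)

    def test_as_amplitude_exceeds_qs(self):
        cfg = SimConfig(seed=4, duration_epochs=60)
        h = generate_hypnogram(cfg)
        x = generate_respiration(h, cfg)
        spans = {"AS": [], "QS": []}
        for i, lab in enumerate(h.labels):
            if lab in spans:
                seg = x[int(i * 30 * 16) : int((i + 1) * 30 * 16)]
                spans[lab].append(np.ptp(seg))
        assert np.median(spans["AS"]) > np.median(spans["QS"])

    def test_sample_count(self):
        x = generate_respiration(qs_only(7), SimConfig(seed=0))
        assert x.size == 7 * 30 * 16


class TestMotion:
    def test_silent_state_all_zero(self):
        cfg = SimConfig(seed=0)
        qs = replace(cfg.state_params["QS"], motion_burst_rate=0.0)
        cfg = replace(cfg, state_params={**cfg.state_params, "QS": qs})
        assert np.all(generate_motion(qs_only(20), cfg) == 0)

    def test_ctw_exceeds_as(self):
        cfg = SimConfig(seed=6, duration_epochs=120)
        h = generate_hypnogram(cfg)
        x = generate_motion(h, cfg)
        sums = {"AS": [], "CTW": []}
        for i, lab in enumerate(h.labels):
            if lab in sums:
                sums[lab].append(x[i * 240 : (i + 1) * 240].sum())
        assert np.mean(sums["CTW"]) > np.mean(sums["AS"])

    def test_nonnegative_and_length(self):
        x = generate_motion(qs_only(3), SimConfig(seed=1))
        assert x.size == 3 * 240 and np.all(x >= 0)

    def test_burst_rate_recovered(self):
        # moderate rate so overlapping bursts (which merge into one nonzero
        # run) stay rare and onset counting estimates the Poisson rate
        cfg = SimConfig(seed=9)
        ctw = replace(cfg.state_params["CTW"], motion_burst_rate=2.0)
        cfg = replace(cfg, state_params={**cfg.state_params, "CTW": ctw})
        h = Hypnogram(labels=tuple(["CTW"] * 400))
        x = generate_motion(h, cfg)
        nz = (x > 0).astype(int)
        onsets = np.sum((nz[1:] == 1) & (nz[:-1] == 0)) + nz[0]
        expected = 2.0 * 400 * 0.5  # bursts/min x 200 min
        assert abs(onsets - expected) < 3 * np.sqrt(expected)


class TestECGWaveform:
    def test_no_peaks_pure_noise(self):
        cfg = SimConfig(seed=0, duration_epochs=1)
        x = generate_ecg_waveform(np.array([]), cfg, 30.0)
        assert x.size == 15000

    def test_deterministic(self):
        cfg = SimConfig(seed=3, duration_epochs=1)
        rp = np.arange(0.5, 29.5, 0.4)
        assert np.array_equal(
            generate_ecg_waveform(rp, cfg, 30.0), generate_ecg_waveform(rp, cfg, 30.0)
        )

    def test_noise_free_roundtrip_with_detector(self):
        from neosleep.preprocess import detect_rpeaks

        cfg = replace(SimConfig(seed=2, duration_epochs=5), ecg_noise_sd=0.0)
        h = generate_hypnogram(cfg)
        rp = generate_rpeaks(h, cfg)
        ecg = generate_ecg_waveform(rp, cfg, h.duration_s)
        det = detect_rpeaks(ecg, cfg.ecg_rate)
        assert det.size == rp.size
        assert np.max(np.abs(det - rp)) <= 1.0 / cfg.ecg_rate + 1e-9


class TestSimulateRecording:
    def test_write_read_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=1, duration_epochs=6)
        rec = simulate_recording(cfg, out_dir=tmp_path / "rec")
        assert read_recording(tmp_path / "rec") == rec

    def test_duration_matches_cohort_scale(self):
        # 589 epochs x 30 s = 4.9 h, a typical full recording
        cfg = SimConfig(seed=0, duration_epochs=589)
        h = generate_hypnogram(cfg)
        assert h.duration_s / 3600 == pytest.approx(4.91, abs=0.01)

    def test_unknown_fraction_relabels(self):
        cfg = SimConfig(seed=5, duration_epochs=200, unknown_fraction=0.1)
        rec = simulate_recording(cfg, include_ecg_waveform=False)
        frac = (rec.annotations["label"] == "Unknown").mean()
        assert frac == pytest.approx(0.1, abs=0.06)

    def test_channel_sample_counts(self):
        rec = simulate_recording(SimConfig(seed=1, duration_epochs=4))
        assert rec.ecg.size == 4 * 30 * 500
        assert rec.resp.size == 4 * 30 * 16
        assert rec.motion.size == 4 * 30 * 8

    def test_cohort_subject_variation_and_determinism(self):
        cfg = SimConfig(seed=8, duration_epochs=3)
        recs1 = simulate_cohort(cfg, n_subjects=3, include_ecg_waveform=False)
        recs2 = simulate_cohort(cfg, n_subjects=3, include_ecg_waveform=False)
        assert [r.subject_id for r in recs1] == ["S1", "S2", "S3"]
        for a, b in zip(recs1, recs2):
            assert a == b
        # different subjects differ
        assert not np.array_equal(recs1[0].resp, recs1[1].resp)
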