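"""Beat segmentation, extrasystole exclusion, conductance calibration."""

import numpy as np
import pytest

from pvloop import (
    SignalRecording,
    SimConfig,
    calibrate_volume,
    detect_rwaves,
    distort_and_noise,
    estimate_alpha,
    filter_extrasystoles,
    intervention_window,
    make_protocol,
    segment_beats,
    simulate_run,
)
from pvloop.beats import Beat, CalibrationError, SegmentationError


def impulse_train(n_s=20, spacing_s=1.0, fs=1000.0, width=10):
    n = int(n_s * fs)
    ecg = np.zeros(n)
    centers = []
    for k in range(int(n_s / spacing_s)):
        c = int(k * spacing_s * fs) + 50
        if c + width >= n:
            break
        for j in range(-width, width + 1):
            ecg[c + j] = max(ecg[c + j], 1.0 - abs(j) / width)
        centers.append(c)
    return ecg, np.array(centers)


class TestDetectRwaves:
    def test_impulse_train_positions(self):
        ecg, centers = impulse_train()
        idx = detect_rwaves(ecg, 1000.0)
        assert len(idx) == len(centers)
        assert np.max(np.abs(idx - centers)) <= 1

    def test_flat_signal_gives_empty(self):
        assert len(detect_rwaves(np.zeros(4000), 1000.0)) == 0

    def test_noisy_train_within_three_samples(self):
        ecg, centers = impulse_train()
        rng = np.random.default_rng(7)
        noisy = ecg + rng.normal(0, 0.1, size=len(ecg))
        idx = detect_rwaves(noisy, 1000.0)
        assert len(idx) == len(centers)
        assert np.max(np.abs(idx - centers)) <= 3

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            detect_rwaves(np.zeros(500), 1000.0)


def _recording_from_r(r_indices, n, fs=1000.0):
    ch = {k: np.zeros(n) for k in ("lvp", "lvv", "lvv_raw", "aop", "aoflow", "ecg")}
    return SignalRecording(fs, ch), np.asarray(r_indices)


class TestSegmentBeats:
    def test_fencepost(self):
        rec, r = _recording_from_r(np.arange(21) * 1000, 21000)
        assert len(segment_beats(rec, r)) == 20

    def test_uniform_rr(self):
        rec, r = _recording_from_r(np.arange(5) * 1000, 5000)
        beats = segment_beats(rec, r)
        assert all(b.rr_s == pytest.approx(1.0) for b in beats)

    def test_partition_no_gaps_no_overlap(self):
        rec, r = _recording_from_r([0, 700, 1500, 2100, 3000], 3200)
        beats = segment_beats(rec, r)
        for b1, b2 in zip(beats[:-1], beats[1:]):
            assert b1.end == b2.start
        assert beats[0].start == 0 and beats[-1].end == 3000

    def test_simulator_rr_matches_heart_rate(self, vload_off_run):
        cfg, rec = vload_off_run
        idx = detect_rwaves(rec.channels["ecg"], rec.fs)
        beats = segment_beats(rec, idx)
        expected = 60.0 / cfg.heart_rate
        assert np.mean([b.rr_s for b in beats]) == pytest.approx(expected, abs=1.5 / rec.fs)

    def test_fewer_than_two_rwaves_raises(self):
        rec, r = _recording_from_r([100], 3000)
        with pytest.raises(SegmentationError):
            segment_beats(rec, r)


class TestFilterExtrasystoles:
    def _beats_from_rr(self, rr_list, fs=1000.0):
        edges = np.concatenate([[0], np.cumsum(np.asarray(rr_list) * fs)]).astype(int)
        z = np.zeros(edges[-1] + 1)
        return [Beat(start=a, end=b, fs=fs, lvp=z[a:b], lvv=z[a:b])
                for a, b in zip(edges[:-1], edges[1:])]

    def test_regular_rhythm_unchanged(self):
        beats = self._beats_from_rr([0.8] * 10)
        assert len(filter_extrasystoles(beats)) == 10

    def test_premature_beat_and_successor_removed(self):
        rr = [0.8] * 4 + [0.48, 1.12] + [0.8] * 4
        beats = self._beats_from_rr(rr)
        kept = filter_extrasystoles(beats)
        assert len(kept) == 8
        assert all(abs(b.rr_s - 0.8) < 1e-9 for b in kept)

    def test_idempotent(self):
        rr = [0.8] * 4 + [0.48, 1.12] + [0.8] * 4
        once = filter_extrasystoles(self._beats_from_rr(rr))
        assert filter_extrasystoles(once) == once

    def test_simulated_extrasystoles_excluded_against_injection_log(self):
        """Two injected premature beats remove exactly four beats."""
        cfg = SimConfig(sda_enabled=False, extrasystole_beats=(6, 12))
        rec = simulate_run(cfg, make_protocol("vload_normal", cfg))
        idx = detect_rwaves(rec.channels["ecg"], rec.fs)
        beats = segment_beats(rec, idx)
        kept = filter_extrasystoles(beats)
        assert len(beats) - len(kept) == 4
        n_es_truth = sum(b.is_extrasystole for b in rec.truth)
        assert n_es_truth == 2


class TestCalibration:
    def test_alpha_ratio_definition(self):
        # three identical synthetic beats: conductance SV 40, flow SV 50
        fs = 1000.0
        n = 800
        v = np.concatenate([np.linspace(100, 60, n // 2), np.linspace(60, 100, n // 2)])
        q = np.zeros(n)
        q[50:450] = 125.0  # 125 mL/s for 0.4 s -> 50 mL
        beats = [Beat(start=i * n, end=(i + 1) * n, fs=fs, lvp=np.zeros(n), lvv=v, aoflow=q)
                 for i in range(3)]
        cal = estimate_alpha(beats)
        assert cal.alpha == pytest.approx(40.0 / 50.0, rel=1e-3)

    def test_alpha_round_trip_against_simulator_truth(self, vload_off_run):
        from pvloop import NoiseSD
        cfg, rec = vload_off_run
        c = cfg.model_copy(update={
            "alpha_true": 0.8, "Vp_true": 30.0,
            "noise_sd": NoiseSD(lvp=0, lvv_raw=0, aop=0, aoflow=0, ecg=0),
        })
        raw = distort_and_noise(rec, c)
        idx = detect_rwaves(raw.channels["ecg"], raw.fs)
        beats = segment_beats(raw, idx, volume_channel="lvv_raw")
        cal = estimate_alpha(beats, baseline=raw.annotation("baseline"))
        assert cal.alpha == pytest.approx(0.8, rel=0.01)

    def test_alpha_identity(self, vload_off_run):
        cfg, rec = vload_off_run
        idx = detect_rwaves(rec.channels["ecg"], rec.fs)
        beats = segment_beats(rec, idx, volume_channel="lvv_raw")
        cal = estimate_alpha(beats, baseline=rec.annotation("baseline"))
        assert cal.alpha == pytest.approx(1.0, rel=0.01)

    def test_zero_flow_raises(self):
        n = 800
        v = np.linspace(100, 60, n)
        beats = [Beat(start=i * n, end=(i + 1) * n, fs=1000.0, lvp=np.zeros(n),
                      lvv=v, aoflow=np.zeros(n)) for i in range(3)]
        with pytest.raises(CalibrationError):
            estimate_alpha(beats)

    @pytest.mark.parametrize("raw, vp, alpha, expected", [
        (110.0, 30.0, 0.8, 100.0),
        (42.0, 0.0, 1.0, 42.0),
    ])
    def test_calibrate_volume_arithmetic(self, raw, vp, alpha, expected):
        assert calibrate_volume(np.array([raw]), alpha, vp)[0] == pytest.approx(expected)

    def test_calibrate_rejects_nonpositive_alpha(self):
        with pytest.raises(CalibrationError):
            calibrate_volume(np.array([1.0]), 0.0, 0.0)


class TestInterventionWindow:
    def _sim_beats(self, rec):
        idx = detect_rwaves(rec.channels["ecg"], rec.fs)
        return segment_beats(rec, idx)

    def test_constant_load_raises(self):
        from pvloop import Protocol
        cfg = SimConfig(sda_enabled=False)
        rec = simulate_run(cfg, Protocol(kind="vload_normal", schedule=(),
                                         total_duration_s=10.0,
                                         annotations=(("intervention", 2.0, 8.0),)))
        with pytest.raises(SegmentationError, match="no load change"):
            intervention_window(self._sim_beats(rec), onset_s=2.0)

    def test_vload_window_matches_occlusion_annotation(self, vload_off_run):
        cfg, rec = vload_off_run
        beats = self._sim_beats(rec)
        win = intervention_window(beats, onset_s=rec.annotation("intervention")[0])
        t0, t1 = rec.annotation("intervention")
        rr = 60.0 / cfg.heart_rate
        assert abs(win[0].t_start_s - t0) <= rr + 1e-6
        assert win[-1].t_start_s <= t1 + 2 * rr

    def test_pload_window_spans_both_phases(self, pload_on_run):
        cfg, rec = pload_on_run
        beats = self._sim_beats(rec)
        win = intervention_window(beats, onset_s=rec.annotation("intervention")[0])
        assert len(win) >= 6
        # covers the SDA phase (first seconds) and reaches into dilation
        assert win[-1].t_start_s - win[0].t_start_s > 3.0
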