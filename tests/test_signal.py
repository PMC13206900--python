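"""Tests of EDA cleaning, decomposition, SCR peak and storm detection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nighteda.config import CleaningConfig, CohortConfig
from nighteda.signal import (
    clean_eda,
    decompose,
    detect_scr_peaks,
    detect_storms,
    process_night,
    summarize_night,
)
from nighteda.simulate import insert_dropout, insert_out_of_bed, simulate_night
from nighteda.types import SCRPeak

from conftest import oracle_f1, oracle_storms

FS = 4.0


def flat_recording(minutes=60, level=1.2, seed=0):
    """A defect-free in-bed recording with constant EDA."""
    cfg = dataclasses.replace(
        CohortConfig(), scr_base_rate=0.0, storm_rate=0.0, noise_sd=0.0,
        tonic_drift_sd=0.0, tonic_level_range=(level, level),
        tonic_night_jitter_sd=0.0, arousal_sd=0.0,
        in_bed_hours_mean=minutes / 60.0, in_bed_hours_sd=0.0, in_bed_hours_min=0.5,
    )
    rec, _ = simulate_night(cfg, seed=seed)
    return rec


class TestCleaning:
    def test_pristine_signal_passes_through(self):
        rec = flat_recording()
        clean = clean_eda(rec)
        assert clean.valid.all()
        np.testing.assert_allclose(clean.values, rec.eda)
        assert clean.usable

    def test_brief_dropout_is_interpolated(self):
        rec = flat_recording()
        insert_dropout(rec, start_s=600.0, length_s=3.0)
        clean = clean_eda(rec)
        # 3 s <= 5 s: run linearly interpolated, nothing left invalid
        assert clean.valid.all()
        assert dict(clean.step_log)["interpolated"] == 12

    def test_long_dropout_stays_invalid(self):
        rec = flat_recording()
        insert_dropout(rec, start_s=600.0, length_s=20.0)
        clean = clean_eda(rec)
        assert int((~clean.valid).sum()) == 80

    def test_short_valid_island_removed(self):
        # a 20-s valid island between two masked dropouts is < 30 s and
        # must be invalidated by the short-segment rule
        rec = flat_recording()
        insert_dropout(rec, start_s=600.0, length_s=10.0)
        insert_dropout(rec, start_s=630.0, length_s=10.0)
        clean = clean_eda(rec)
        island = slice(int(610 * FS), int(630 * FS))
        assert not clean.valid[island].any()
        assert dict(clean.step_log)["short_segment"] >= 80

    def test_spike_artifact_masked_and_interpolated(self):
        rec = flat_recording(level=1.2)
        i = int(900 * FS)
        rec.eda[i] += 3.0  # 12 µS/s excursion
        clean = clean_eda(rec)
        assert dict(clean.step_log)["artifact"] > 0
        # spike + 2 s padding is a ~4 s invalid run: interpolated back to
        # the flat 1.2 µS baseline
        assert clean.valid[i]
        assert clean.values[i] == pytest.approx(1.2, rel=1e-6)

    def test_out_of_bed_samples_invalidated(self):
        rec = flat_recording(minutes=120)
        insert_out_of_bed(rec, start_min=50, length_min=10, eda_offset=0.5)
        clean = clean_eda(rec)
        sl = slice(int(50 * 60 * FS), int(60 * 60 * FS))
        assert not clean.valid[sl].any()

    def test_unusable_when_too_little_signal(self):
        rec = flat_recording(minutes=40)
        insert_dropout(rec, start_s=0.0, length_s=20 * 60.0)
        clean = clean_eda(rec)
        assert not clean.usable
        assert clean.unusable_reason == "insufficient_valid_in_bed_signal"


class TestDecompose:
    def test_constant_signal_splits_trivially(self):
        x = np.full(2000, 1.2)
        tonic, phasic = decompose(x, np.ones_like(x, bool), FS)
        np.testing.assert_allclose(tonic, 1.2)
        np.testing.assert_allclose(phasic, 0.0, atol=1e-15)

    def test_single_kernel_survives_median(self):
        # independent computation: a 0.05 µS kernel (1 s rise, tau 3 s)
        # retains a 0.0344 µS phasic maximum after the 8-s moving median
        from nighteda.simulate import _scr_kernel

        x = np.full(4000, 1.2)
        k = _scr_kernel(0.05, CohortConfig(), FS)
        x[2000 : 2000 + len(k)] += k
        _, phasic = decompose(x, np.ones_like(x, bool), FS)
        assert np.nanmax(phasic) == pytest.approx(0.03443, abs=5e-4)

    def test_slow_ramp_absorbed_by_tonic(self):
        x = np.linspace(0.0, 1.0, int(3600 * FS))
        _, phasic = decompose(x, np.ones_like(x, bool), FS)
        assert np.nanmax(np.abs(phasic)) < 0.001

    def test_additivity_at_valid_samples(self):
        rng = np.random.default_rng(0)
        x = np.abs(rng.normal(1.0, 0.3, 8000)).cumsum() / 100
        valid = np.ones_like(x, bool)
        for start in rng.integers(0, 7500, size=5):
            valid[start : start + int(rng.integers(10, 400))] = False
        tonic, phasic = decompose(x, valid, FS)
        np.testing.assert_allclose((tonic + phasic)[valid], x[valid], atol=1e-9)
        assert np.isnan(tonic[~valid]).all()

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            decompose(np.ones(100), np.zeros(100, bool), FS)


def bump(n, at, amplitude, width=8):
    """A triangular trough-to-peak excursion on a flat phasic trace."""
    x = np.zeros(n)
    ramp = np.linspace(0.0, amplitude, width)
    x[at : at + width] = ramp
    x[at + width : at + 2 * width - 1] = ramp[-2::-1]
    return x


class TestPeakDetection:
    def test_flat_signal_has_no_peaks(self):
        assert detect_scr_peaks(np.zeros(1000), np.ones(1000, bool), FS) == []

    @pytest.mark.parametrize("amplitude,n_expected", [(0.004, 0), (0.006, 1)])
    def test_amplitude_floor(self, amplitude, n_expected):
        x = bump(800, 400, amplitude)
        peaks = detect_scr_peaks(x, np.ones(800, bool), FS)
        assert len(peaks) == n_expected

    def test_refractory_keeps_larger_peak(self):
        # two excursions 0.5 s apart (amplitudes 0.02 and 0.01 µS):
        # exactly the larger one survives the 1-s refractory
        x = np.zeros(800)
        x[398:401] = [0.005, 0.012, 0.02]  # peak at index 400
        x[401] = 0.002
        x[402] = 0.01  # peak at index 402, 0.5 s later
        x[403] = 0.001
        peaks = detect_scr_peaks(x, np.ones(800, bool), FS, min_separation=1.0)
        assert len(peaks) == 1
        assert peaks[0].amplitude == pytest.approx(0.02)
        assert peaks[0].peak_time == pytest.approx(400 / FS)

    def test_peaks_never_span_invalid_gaps(self):
        x = bump(800, 396, 0.05)
        valid = np.ones(800, bool)
        valid[404] = False  # cut through the bump
        peaks = detect_scr_peaks(x, valid, FS)
        for p in peaks:
            assert valid[int(round(p.peak_time * FS))]
            assert valid[int(round(p.trough_time * FS))]

    def test_matches_bruteforce_oracle_on_random_signals(self):
        # independent oracle: enumerate strict local extrema, apply the
        # amplitude floor, then transcribe the refractory rule as its
        # recursive dominance fixed point — a candidate survives unless a
        # surviving higher-priority candidate (larger amplitude; ties to
        # the earlier peak) lies closer than min_sep
        def brute(x, fs, min_amp, min_sep):
            cands = []
            last_min = 0
            for i in range(1, len(x) - 1):
                if x[i] < x[i - 1] and x[i] < x[i + 1]:
                    last_min = i
                if x[i] > x[i - 1] and x[i] > x[i + 1]:
                    amp = x[i] - x[last_min]
                    if amp >= min_amp:
                        cands.append((i / fs, amp))

            from functools import lru_cache

            order = sorted(range(len(cands)), key=lambda j: (-cands[j][1], cands[j][0]))
            rank = {j: r for r, j in enumerate(order)}

            @lru_cache(maxsize=None)
            def survives(j):
                return not any(
                    rank[k] < rank[j]
                    and abs(cands[k][0] - cands[j][0]) < min_sep
                    and survives(k)
                    for k in range(len(cands))
                    if k != j
                )

            return sorted(cands[j][0] for j in range(len(cands)) if survives(j))

        rng = np.random.default_rng(42)
        for _ in range(30):
            # 2-min random-walk signal with many small excursions
            n = 480
            x = np.cumsum(rng.normal(0, 0.004, n))
            expected = brute(x, FS, 0.005, 1.0)
            got = [p.peak_time for p in detect_scr_peaks(x, np.ones(n, bool), FS)]
            assert got == pytest.approx(expected)


class TestStormDetection:
    def test_three_peaks_in_one_epoch_is_a_storm(self):
        peaks = [SCRPeak(t, t - 1, 0.05, 0.05) for t in (2.0, 10.0, 25.0)]
        storms = detect_storms(peaks, [(0.0, 3600.0)])
        assert len(storms) == 1
        s = storms[0]
        assert (s.n_epochs, s.n_peaks) == (1, 3)
        assert s.duration_min == pytest.approx(0.5)

    def test_two_peaks_per_epoch_is_never_a_storm(self):
        peaks = [
            SCRPeak(t, t - 1, 0.05, 0.05)
            for e in range(0, 3600, 30)
            for t in (e + 5.0, e + 20.0)
        ]
        assert detect_storms(peaks, [(0.0, 3600.0)]) == []

    def test_positive_epochs_merge_across_four_minute_gap(self):
        times = [1.0, 5.0, 20.0, 272.0, 280.0, 295.0]
        peaks = [SCRPeak(t, t - 0.5, 0.05, 0.05) for t in times]
        storms = detect_storms(peaks, [(0.0, 3600.0)])
        assert len(storms) == 1
        assert (storms[0].start_time, storms[0].end_time) == (0.0, 300.0)
        assert storms[0].duration_min == pytest.approx(5.0)
        assert storms[0].n_epochs == 2

    def test_storms_never_bridge_in_bed_intervals(self):
        times = [1.0, 5.0, 20.0, 3631.0, 3635.0, 3650.0]
        peaks = [SCRPeak(t, t - 0.5, 0.05, 0.05) for t in times]
        storms = detect_storms(peaks, [(0.0, 30.0), (3630.0, 3700.0)])
        assert len(storms) == 2

    def test_matches_bruteforce_oracle_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            span = float(rng.uniform(600, 12 * 3600))
            n = int(rng.integers(0, 300))
            times = np.sort(rng.uniform(0, span, n))
            # add clusters so positive epochs actually occur
            for _c in range(int(rng.integers(0, 6))):
                c = rng.uniform(0, span - 60)
                times = np.sort(np.r_[times, rng.uniform(c, c + 45, int(rng.integers(3, 12)))])
            peaks = [SCRPeak(t, t - 0.5, 0.05, 0.05) for t in times]
            got = detect_storms(peaks, [(0.0, span)])
            exp = oracle_storms(times, 0.0, span)
            assert [(s.start_time, s.end_time, s.n_epochs) for s in got] == exp


class TestSummaries:
    def test_empty_night_summary(self):
        rec = flat_recording(minutes=480)
        clean = clean_eda(rec)
        s = summarize_night(clean, [], [])
        assert s.storm_count == 0
        assert s.storm_rate == 0.0
        assert s.mean_storm_duration == 0.0
        assert s.no_peaks
        assert s.median_total_eda == pytest.approx(np.median(clean.values))

    def test_peak_rate_is_per_valid_hour(self):
        rec = flat_recording(minutes=480)
        clean = clean_eda(rec)
        peaks = [SCRPeak(10.0 * i, 10.0 * i - 1, 0.02, 0.02) for i in range(1, 41)]
        s = summarize_night(clean, peaks, [])
        assert s.scr_peak_rate == pytest.approx(40 / 8.0)

    def test_exclusion_no_event_in_out_of_bed_minutes(self):
        cfg = CohortConfig()
        for seed in range(3):
            rec, _ = simulate_night(cfg, seed=seed)
            insert_out_of_bed(rec, 100, 15, cfg.out_of_bed_eda_offset)
            _, peaks, storms, _ = process_night(rec)
            out = ~rec.in_bed_minute_mask()
            for p in peaks:
                assert not out[int(p.peak_time // 60)]
            for s in storms:
                for m in range(int(s.start_time // 60), int((s.end_time - 1) // 60) + 1):
                    assert not out[m]

    def test_recovery_storm_count_within_one(self):
        # truth-aware recovery at default noise, quick version
        cfg = CohortConfig()
        ok = 0
        for seed in range(10):
            rec, truth = simulate_night(cfg, seed=seed)
            _, _, storms, _ = process_night(rec)
            ok += abs(len(storms) - len(truth.storm_windows)) <= 1
        assert ok >= 9
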