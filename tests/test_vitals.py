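import numpy as np
import pytest
from scipy.signal import find_peaks

from bcgsleep import (
    LABEL_VALID,
    SignalRecord,
    SimulationConfig,
    detect_r_peaks_pan_tompkins,
    estimate_hr_window,
    estimate_rr_window,
    estimate_vitals,
    extract_cardiac_component,
    extract_respiratory_component,
    label_artifacts,
    reference_series,
    simulate_recording,
    slice_windows,
    truth_series,
    window_samples,
)

FS = 50.0
T30 = np.arange(0, 30, 1 / FS)


class TestExtraction:
    def test_level4_smooth_rejects_10hz(self):
        x = np.sin(2 * np.pi * 10.0 * T30)
        out = extract_cardiac_component(x, FS)
        assert np.sum(out ** 2) < 0.05 * np.sum(x ** 2)

    def test_constant_input_gives_zero_cardiac(self):
        out = extract_cardiac_component(np.full(1500, 7.0), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="support"):
            extract_cardiac_component(np.zeros(50), FS)

    def test_respiratory_passband_preserves_quarter_hz(self):
        x = np.sin(2 * np.pi * 0.25 * T30)
        out = extract_respiratory_component(x, FS)
        assert np.corrcoef(x, out)[0, 1] > 0.99

    def test_constant_input_gives_zero_respiratory(self):
        out = extract_respiratory_component(np.full(1500, 7.0), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_one_peak_per_beat_in_well_coupled_window(self):
        cfg = SimulationConfig(duration_s=120.0, seed=3, amp_log_sd=0.0,
                               resp_amp_mv=100.0)
        bcg, *_, truth = simulate_recording(cfg)
        grid = slice_windows(bcg, 30.0, 15.0)
        for i in range(len(grid)):
            c = extract_cardiac_component(window_samples(bcg, grid, i), FS)
            mad = np.median(np.abs(c - np.median(c)))
            peaks, _ = find_peaks(c, distance=int(FS / 3), prominence=0.02 * mad)
            s = grid.starts_s[i]
            n_true = int(np.sum((truth.beat_times_s >= s)
                                & (truth.beat_times_s < s + 30.0)))
            assert abs(len(peaks) - n_true) <= 1

    def test_breath_peak_count_matches_truth(self):
        cfg = SimulationConfig(duration_s=120.0, seed=3, amp_log_sd=0.0)
        bcg, *_, truth = simulate_recording(cfg)
        grid = slice_windows(bcg, 30.0, 15.0)
        resp = extract_respiratory_component(window_samples(bcg, grid, 0), FS)
        mad = np.median(np.abs(resp - np.median(resp)))
        peaks, _ = find_peaks(resp, distance=int(FS * 1.5), prominence=0.02 * mad)
        n_true = int(np.sum((truth.breath_times_s >= 0)
                            & (truth.breath_times_s < 30.0)))
        assert abs(len(peaks) - n_true) <= 1


class TestRateEstimators:
    def test_impulse_train_exact_rate(self):
        x = np.zeros(1500)
        x[::50] = 1.0
        assert estimate_hr_window(x, FS) == pytest.approx(60.0)

    def test_quarter_hz_sinusoid_is_15_brpm(self):
        x = np.sin(2 * np.pi * 0.25 * T30)
        assert estimate_rr_window(x, FS) == pytest.approx(15.0, abs=0.1)

    def test_too_few_peaks_invalid(self):
        x = np.zeros(1500)
        x[[300, 900]] = 1.0
        assert np.isnan(estimate_hr_window(x, FS))

    def test_flat_signal_invalid(self):
        assert np.isnan(estimate_rr_window(np.zeros(1500), FS))
        assert np.isnan(estimate_hr_window(np.zeros(1500), FS))

    @pytest.mark.parametrize("scale", [1e-3, 1.0, 1e3])
    def test_amplitude_scale_invariance(self, scale, clean_recording):
        _, (bcg, *_ ) = clean_recording
        w = bcg.samples[:1500]
        c = extract_cardiac_component(w, FS)
        r = extract_respiratory_component(w, FS)
        assert estimate_hr_window(c * scale, FS) == estimate_hr_window(c, FS)
        assert estimate_rr_window(r * scale, FS) == estimate_rr_window(r, FS)


class TestPanTompkins:
    def test_clean_ecg_recovery(self):
        cfg = SimulationConfig(duration_s=300.0, hr_bpm=60.0, seed=13)
        _, ecg, _, truth = simulate_recording(cfg)
        beats = detect_r_peaks_pan_tompkins(ecg)
        assert abs(beats.size - truth.beat_times_s.size) <= 1
        matched = sum(np.min(np.abs(beats - t)) < 0.10
                      for t in truth.beat_times_s)
        assert matched / truth.beat_times_s.size >= 0.99  # sensitivity
        assert matched / beats.size >= 0.99               # positive predictivity

    def test_zero_signal_gives_no_beats(self):
        rec = SignalRecord(samples=np.zeros(3000), fs=FS)
        assert detect_r_peaks_pan_tompkins(rec).size == 0

    def test_low_rate_rejected(self):
        rec = SignalRecord(samples=np.random.default_rng(0).normal(size=500),
                           fs=30.0)
        with pytest.raises(ValueError, match="40"):
            detect_r_peaks_pan_tompkins(rec)

    def test_recovers_after_artifact_burst(self):
        cfg = SimulationConfig(duration_s=300.0, hr_bpm=60.0, seed=14)
        _, ecg, _, truth = simulate_recording(cfg)
        noisy = ecg.samples.copy()
        rng = np.random.default_rng(99)
        noisy[int(150 * FS): int(155 * FS)] += rng.normal(0, 5.0, int(5 * FS))
        beats = detect_r_peaks_pan_tompkins(SignalRecord(samples=noisy, fs=FS))
        outside = truth.beat_times_s[
            (truth.beat_times_s < 149.0) | (truth.beat_times_s > 156.0)]
        matched = sum(np.min(np.abs(beats - t)) < 0.10 for t in outside)
        assert matched / outside.size >= 0.98


class TestSeriesEstimation:
    def test_all_artifact_windows_invalid(self, clean_recording):
        _, (bcg, *_ ) = clean_recording
        grid = slice_windows(bcg, 30.0, 15.0)
        labels = label_artifacts(bcg, grid)
        labels.labels[:] = "motion_artifact"
        hr, rr = estimate_vitals(bcg, labels)
        assert not hr.valid_mask.any() and not rr.valid_mask.any()

    def test_estimates_deterministic(self, clean_recording):
        _, (bcg, *_ ) = clean_recording
        grid = slice_windows(bcg, 30.0, 15.0)
        labels = label_artifacts(bcg, grid)
        hr1, _ = estimate_vitals(bcg, labels)
        hr2, _ = estimate_vitals(bcg, labels)
        np.testing.assert_array_equal(hr1.values, hr2.values)

    def test_valid_windows_follow_artifact_labels(self, clean_recording):
        _, (bcg, *_ ) = clean_recording
        grid = slice_windows(bcg, 30.0, 15.0)
        labels = label_artifacts(bcg, grid)
        hr, rr = estimate_vitals(bcg, labels)
        ok = labels.mask(LABEL_VALID)
        # no rate escapes a suppressed window; nearly every retained
        # window yields a plausible rate
        assert not (hr.valid_mask & ~ok).any()
        assert (ok & ~hr.valid_mask).sum() <= 2
        assert (ok & ~rr.valid_mask).sum() <= 2

    def test_reference_series_recover_configured_rates(self, clean_recording):
        cfg, (bcg, ecg, effort, truth) = clean_recording
        grid = slice_windows(bcg, 30.0, 15.0)
        hr_ref = reference_series(ecg, grid, kind="ecg")
        rr_ref = reference_series(effort, grid, kind="effort")
        assert np.nanmedian(hr_ref.values) == pytest.approx(cfg.hr_bpm, abs=1.5)
        assert np.nanmedian(rr_ref.values) == pytest.approx(cfg.rr_brpm, abs=1.0)

    def test_misaligned_grid_rejected(self, clean_recording):
        _, (bcg, ecg, *_ ) = clean_recording
        long_rec = SignalRecord(samples=np.zeros(int(700 * FS)), fs=FS)
        grid = slice_windows(long_rec, 30.0, 15.0)
        with pytest.raises(ValueError, match="grid"):
            reference_series(ecg, grid, kind="ecg")

    def test_truth_series_uses_same_estimator(self, clean_recording):
        _, (bcg, *_, truth) = clean_recording
        grid = slice_windows(bcg, 30.0, 15.0)
        ts = truth_series(truth.beat_times_s, grid, "hr")
        assert ts.valid_mask.sum() == len(grid)
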