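import numpy as np
import pytest

from bcgsleep import (
    ApneaModel,
    EventAnnotations,
    SignalRecord,
    WindowGrid,
    compute_aad,
    detect_events,
    estimate_ahi,
    events_to_windows,
    fit_threshold,
    slice_windows,
)
from bcgsleep.apnea import ranked_bin_centers, subslice_spread

FS = 50.0


def segments_with_aads(aads, seg_len_s=20.0, fs=FS):
    """Signal whose consecutive segments have the prescribed AADs.

    An alternating +/-c pattern has mean 0 and mean |x| = c = AAD.
    """
    n = int(seg_len_s * fs)
    return np.concatenate([np.tile([a, -a], n // 2) for a in aads])


class TestAad:
    @pytest.mark.parametrize("x,expected", [
        ([5, 5, 5, 5], 0.0),
        ([1, 2, 3, 4], 1.0),        # mean 2.5 -> (1.5+.5+.5+1.5)/4
        ([7], 0.0),
    ])
    def test_values(self, x, expected):
        assert compute_aad(np.array(x, float)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_aad(np.array([]))

    def test_translation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        assert compute_aad(x + 123.4) == pytest.approx(compute_aad(x))


class TestFitThreshold:
    def test_ranked_bins_hand_example(self):
        # AAD multiset {1,1,1,2,2,3}, 3 equal bins over [0,3]:
        # edges 0|1|2|3 -> counts [0,3,3]; stable descending rank puts the
        # lower-AAD bin first, so k=1 -> 1.5 (mode) and k=2 -> 2.5 (the
        # bin holding the 2s and the closed top edge)
        ranked = ranked_bin_centers(np.array([1, 1, 1, 2, 2, 3], float), 3)
        assert ranked[0] == pytest.approx(1.5)
        assert ranked[1] == pytest.approx(2.5)

    def test_order_free(self):
        rng = np.random.default_rng(1)
        aads = rng.uniform(0.1, 10.0, 200)
        shuffled = rng.permutation(aads)
        np.testing.assert_allclose(ranked_bin_centers(aads, 50),
                                   ranked_bin_centers(shuffled, 50))

    def test_constant_signal_rejected(self):
        rec = SignalRecord(samples=np.full(int(120 * FS), 3.0), fs=FS)
        with pytest.raises(ValueError, match="zero"):
            fit_threshold(rec)

    def test_too_few_bins_reported(self, regime_recording):
        _, (bcg, *_ ) = regime_recording
        from bcgsleep import extract_respiratory_component
        resp = bcg.copy_with(
            samples=extract_respiratory_component(bcg.samples, bcg.fs))
        with pytest.raises(ValueError, match="non-empty"):
            fit_threshold(resp, n_bins=2, histogram_index_k=6)

    def test_fit_sets_positive_threshold(self, regime_recording):
        _, (bcg, *_ ) = regime_recording
        from bcgsleep import extract_respiratory_component
        resp = bcg.copy_with(
            samples=extract_respiratory_component(bcg.samples, bcg.fs))
        model = fit_threshold(resp)
        assert model.aad_threshold_T > 0


class TestDetect:
    def _series(self, aads):
        rec = SignalRecord(samples=segments_with_aads(aads), fs=FS)
        model = ApneaModel()
        model.aad_threshold_T = 10.0
        return detect_events(rec, model)

    def test_hand_example_fires(self):
        # subslice AADs {12, 11, 20}: sorted {11,12,20}, 20-12=8 > 0.45*10
        series = self._series([12.0, 11.0, 20.0])
        assert series.predicted[0]

    def test_equal_subslices_do_not_fire(self):
        series = self._series([15.0, 15.0, 15.0])
        assert not series.predicted[0]

    def test_unfitted_model_rejected(self):
        rec = SignalRecord(samples=segments_with_aads([1, 2, 3]), fs=FS)
        with pytest.raises(ValueError, match="unfitted"):
            detect_events(rec, ApneaModel())

    def test_monotone_in_fraction(self, regime_recording):
        _, (bcg, *_ ) = regime_recording
        from bcgsleep import extract_respiratory_component
        resp = bcg.copy_with(
            samples=extract_respiratory_component(bcg.samples, bcg.fs))
        model = fit_threshold(resp)
        prev = None
        for f in [0.2, 0.45, 0.7, 0.95]:
            model.fraction_f = f
            pred = detect_events(resp, model).predicted
            if prev is not None:
                assert np.all(prev | ~pred)  # shrinking positive set
            prev = pred

    def test_offset_invariant_and_joint_scaling(self):
        aads = [12.0, 11.0, 20.0, 5.0, 5.0, 30.0]
        rec = SignalRecord(samples=segments_with_aads(aads), fs=FS)
        model = ApneaModel()
        model.aad_threshold_T = 10.0
        base = detect_events(rec, model).predicted
        shifted = SignalRecord(samples=rec.samples + 77.0, fs=FS)
        np.testing.assert_array_equal(detect_events(shifted, model).predicted,
                                      base)
        scaled = SignalRecord(samples=rec.samples * 3.0, fs=FS)
        model3 = ApneaModel()
        model3.aad_threshold_T = 30.0
        np.testing.assert_array_equal(detect_events(scaled, model3).predicted,
                                      base)


class TestEventsToWindows:
    def _grid(self, starts, window=60.0):
        return WindowGrid(window_len_s=window, hop_s=window / 2,
                          starts_s=np.array(starts))

    def test_contained_event_positive(self):
        ev = EventAnnotations(events=[(65.0, 15.0, "hypopnea")])
        ref = events_to_windows(ev, self._grid([60.0]), min_overlap_s=0.0)
        assert ref[0]

    def test_disjoint_event_negative(self):
        ev = EventAnnotations(events=[(0.0, 10.0, "hypopnea")])
        ref = events_to_windows(ev, self._grid([60.0]), min_overlap_s=0.0)
        assert not ref[0]

    def test_boundary_straddling_event_hits_both(self):
        ev = EventAnnotations(events=[(55.0, 10.0, "hypopnea")])
        ref = events_to_windows(ev, self._grid([0.0, 30.0]), min_overlap_s=0.0)
        assert ref.tolist() == [True, True]

    def test_default_requires_apnea_length_overlap(self):
        ev = EventAnnotations(events=[(55.0, 12.0, "hypopnea")])
        ref = events_to_windows(ev, self._grid([0.0, 30.0]))
        assert ref.tolist() == [False, True]


class TestAhi:
    @pytest.mark.parametrize("n,tst,ahi,label", [
        (30, 3600.0, 30.0, "severe"),
        (0, 3600.0, 0.0, "normal"),
        (14, 3600.0, 14.0, "mild"),
        (15, 3600.0, 15.0, "moderate"),
        (4, 3600.0, 4.0, "normal"),
    ])
    def test_classes(self, n, tst, ahi, label):
        ev = EventAnnotations(
            events=[(60.0 * i, 15.0, "hypopnea") for i in range(n)],
            total_sleep_time_s=tst)
        got_ahi, got_label = estimate_ahi(ev)
        assert got_ahi == pytest.approx(ahi)
        assert got_label == label

    def test_zero_sleep_time_rejected(self):
        with pytest.raises(ValueError):
            estimate_ahi(EventAnnotations(events=[], total_sleep_time_s=0.0))
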