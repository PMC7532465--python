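"""Per-window heart-rate and respiratory-rate estimation.

The cardiac component of a BCG window is the level-4 smooth
(approximation) of an undecimated Daubechies-4 wavelet decomposition —
at 50 Hz this passes roughly 0–1.56 Hz, which contains the per-beat
envelope of the cardioballistic complex — detrended by a 2-s centered
moving average to suppress the respiratory baseline.  The respiratory
component is a zero-phase band-pass of ~0.1–0.8 Hz, which also removes
the slow nonlinear trend.

Rates come from the median inter-peak interval inside each 30-s window
(robust to a single missed or spurious peak); peak prominence thresholds
are MAD-relative, making the estimators invariant to global amplitude
scaling.  Reference rates use the Pan–Tompkins QRS detector on the ECG
channel and the same peak logic on the thoracic-effort belt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .io import SignalRecord
from .preprocess import (
    LABEL_VALID,
    WindowGrid,
    WindowLabelSeries,
    window_samples,
)

__all__ = [
    "VitalSeries",
    "extract_cardiac_component",
    "extract_respiratory_component",
    "estimate_hr_window",
    "estimate_rr_window",
    "detect_r_peaks_pan_tompkins",
    "reference_series",
    "estimate_vitals",
    "HR_BOUNDS_BPM",
    "RR_BOUNDS_BRPM",
]

#: Plausibility bounds; per-window rates outside are marked invalid.
HR_BOUNDS_BPM = (40.0, 180.0)
RR_BOUNDS_BRPM = (6.0, 40.0)


@dataclass
class VitalSeries:
    """Per-window rates on a grid; NaN where a window was unusable."""

    grid: WindowGrid
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.size != len(self.grid) or self.valid_mask.size != self.values.size:
            raise ValueError("values/valid_mask must match the grid length")


def _swt_smooth(x: np.ndarray, level: int = 4, wavelet: str = "db4") -> np.ndarray:
    """Level-``level`` smooth of a shift-invariant wavelet decomposition."""
    n = x.size
    block = 2 ** level
    pad = (-n) % block
    # reflect-pad to a multiple of 2**level, plus a guard block each side
    guard = block
    xp = np.pad(x, (guard, guard + pad), mode="reflect")
    coeffs = pywt.swt(xp, wavelet, level=level, trim_approx=True, norm=True)
    smooth = coeffs[0]
    return smooth[guard: guard + n]


def extract_cardiac_component(window: np.ndarray, fs: float,
                              level: int = 4, wavelet: str = "db4",
                              detrend_s: float = 2.0) -> np.ndarray:
    """Cardiac (beat-train) component of one artifact-free BCG window."""
    window = np.asarray(window, dtype=float)
    if window.size < int(round(detrend_s * fs)) + 2 ** level:
        raise ValueError("window shorter than the filter support")
    smooth = _swt_smooth(window, level=level, wavelet=wavelet)
    size = int(round(detrend_s * fs)) | 1  # odd-length centered average
    baseline = uniform_filter1d(smooth, size=size, mode="nearest")
    return smooth - baseline


def extract_respiratory_component(window: np.ndarray, fs: float,
                                  band: tuple[float, float] = (0.1, 0.8),
                                  order: int = 4) -> np.ndarray:
    """Respiratory effort component: zero-phase band-pass of the raw window."""
    window = np.asarray(window, dtype=float)
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    if window.size <= 3 * (2 * sos.shape[0] + 1):
        raise ValueError("window shorter than the filter support")
    # generous reflect padding keeps the slow passband clean at the edges
    padlen = min(window.size - 1, int(round(10.0 * fs)))
    return sosfiltfilt(sos, window, padlen=padlen)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


#: A window whose inter-peak intervals spread beyond this 75th/25th
#: percentile ratio is unreliable (runs of missed or split peaks) and is
#: marked invalid rather than reported at a biased rate.
INTERVAL_DISPERSION_MAX = 1.5


def _rate_from_peaks(x: np.ndarray, fs: float, max_rate_per_min: float,
                     min_peaks: int, prominence_k: float) -> float:
    """60 / median inter-peak interval; NaN when too few or erratic peaks."""
    distance = max(1, int(round(fs * 60.0 / max_rate_per_min)))
    mad = _mad(x)
    prominence = prominence_k * mad if mad > 0 else None
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence)
    if peaks.size < min_peaks:
        return float("nan")
    intervals = np.diff(peaks)
    q25, q75 = np.percentile(intervals, [25, 75])
    if q25 > 0 and q75 / q25 > INTERVAL_DISPERSION_MAX:
        return float("nan")
    return 60.0 / (float(np.median(intervals)) / fs)


def estimate_hr_window(cardiac: np.ndarray, fs: float,
                       prominence_k: float = 0.02) -> float:
    """Heart rate (bpm) of one window from its cardiac component.

    Requires at least 3 detected beats; otherwise NaN.
    """
    return _rate_from_peaks(np.asarray(cardiac, dtype=float), fs,
                            max_rate_per_min=180.0, min_peaks=3,
                            prominence_k=prominence_k)


def estimate_rr_window(resp: np.ndarray, fs: float,
                       prominence_k: float = 0.02) -> float:
    """Respiratory rate (breaths/min); needs at least 2 full intervals."""
    return _rate_from_peaks(np.asarray(resp, dtype=float), fs,
                            max_rate_per_min=40.0, min_peaks=3,
                            prominence_k=prominence_k)


def detect_r_peaks_pan_tompkins(ecg: SignalRecord,
                                band: tuple[float, float] = (5.0, 15.0),
                                integration_s: float = 0.150,
                                refractory_s: float = 0.200) -> np.ndarray:
    """R-peak times (s) via the classic Pan–Tompkins stages.

    Band-pass, differentiate, square, moving-window integrate, then
    dual adaptive thresholds with missed-beat search-back.  Peak times
    are refined to the band-passed-signal maximum near each detection.
    """
    fs = ecg.fs
    if fs < 40.0:
        raise ValueError(f"Pan-Tompkins needs fs >= 40 Hz, got {fs}")
    x = ecg.samples - np.mean(ecg.samples)
    if np.allclose(x, 0.0):
        return np.array([])
    high = min(band[1], 0.45 * fs)
    sos = butter(2, (band[0], high), btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    mwi = uniform_filter1d(sq, size=max(1, int(round(integration_s * fs))),
                           mode="nearest")

    refractory = int(round(refractory_s * fs))
    cand, _ = find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.array([])

    # initial threshold estimates from the first two seconds
    lead = mwi[: int(2 * fs)] if mwi.size > int(2 * fs) else mwi
    spki = 0.5 * float(np.max(lead))
    npki = 0.5 * float(np.mean(lead))
    beats: list[int] = []
    rr_hist: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in cand:
        peak = mwi[idx]
        if peak > threshold1():
            if beats and (idx - beats[-1]) < refractory:
                continue
            # search-back first: did we skip a beat since the last one?
            beats.append(int(idx))
            if len(beats) >= 2:
                rr_hist.append(beats[-1] - beats[-2])
                rr_hist[:] = rr_hist[-8:]
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki
            # missed-beat search-back; on failure decay the signal-peak
            # estimate so thresholds recover after a large artifact
            if beats and rr_hist:
                rr_avg = float(np.mean(rr_hist))
                if (idx - beats[-1]) > 1.66 * rr_avg:
                    seg = [c for c in cand
                           if beats[-1] + refractory <= c <= idx]
                    recovered = False
                    if seg:
                        best = max(seg, key=lambda c: mwi[c])
                        if mwi[best] > 0.5 * threshold1():
                            beats.append(int(best))
                            rr_hist.append(beats[-1] - beats[-2])
                            rr_hist[:] = rr_hist[-8:]
                            spki = 0.25 * mwi[best] + 0.75 * spki
                            beats.sort()
                            recovered = True
                    if not recovered:
                        spki = max(0.5 * spki, npki)

    # refine beat locations to the nearby band-passed maximum
    half = int(round(0.10 * fs))
    refined = []
    for b in beats:
        i0, i1 = max(0, b - half), min(bp.size, b + half + 1)
        refined.append(i0 + int(np.argmax(bp[i0:i1])))
    refined = np.unique(refined)
    return ecg.start_time + refined / fs


def _rate_series_from_times(times: np.ndarray, grid: WindowGrid,
                            min_peaks: int, bounds: tuple[float, float]) -> VitalSeries:
    values = np.full(len(grid), np.nan)
    for i, s in enumerate(grid.starts_s):
        sel = times[(times >= s) & (times < s + grid.window_len_s)]
        if sel.size >= min_peaks:
            values[i] = 60.0 / float(np.median(np.diff(sel)))
    valid = np.isfinite(values) & (values >= bounds[0]) & (values <= bounds[1])
    values[~valid] = np.nan
    return VitalSeries(grid=grid, values=values, valid_mask=valid)


def reference_series(record: SignalRecord, grid: WindowGrid,
                     kind: str | None = None) -> VitalSeries:
    """Reference HR (from ECG R-peaks) or RR (from the effort belt).

    ``kind`` is ``"ecg"`` or ``"effort"``; defaults to the record's
    channel name.
    """
    kind = kind or record.channel_name
    if grid.starts_s.size and grid.ends_s[-1] > record.duration_s + 1e-9:
        raise ValueError("grid extends beyond the reference record")
    if kind == "ecg":
        beats = detect_r_peaks_pan_tompkins(record)
        return _rate_series_from_times(beats, grid, min_peaks=3,
                                       bounds=HR_BOUNDS_BPM)
    if kind == "effort":
        values = np.full(len(grid), np.nan)
        for i in range(len(grid)):
            w = window_samples(record, grid, i)
            values[i] = estimate_rr_window(w, record.fs)
        valid = (np.isfinite(values)
                 & (values >= RR_BOUNDS_BRPM[0]) & (values <= RR_BOUNDS_BRPM[1]))
        values[~valid] = np.nan
        return VitalSeries(grid=grid, values=values, valid_mask=valid)
    raise ValueError(f"unknown reference kind {kind!r}")


def truth_series(times: np.ndarray, grid: WindowGrid, kind: str) -> VitalSeries:
    """Per-window rate from ground-truth beat or breath times.

    Applies the same median-interval estimator and plausibility bounds
    as the signal path, so truth and estimate are directly comparable.
    """
    bounds = HR_BOUNDS_BPM if kind == "hr" else RR_BOUNDS_BRPM
    min_peaks = 3
    return _rate_series_from_times(np.asarray(times, dtype=float), grid,
                                   min_peaks, bounds)


def estimate_vitals(bcg: SignalRecord, labels: WindowLabelSeries,
                    prominence_k: float = 0.02) -> tuple[VitalSeries, VitalSeries]:
    """Per-window (HR, RR) from the BCG, restricted to valid windows."""
    grid = labels.grid
    if len(labels.labels) != len(grid):
        raise ValueError("label series does not match its grid")
    hr = np.full(len(grid), np.nan)
    rr = np.full(len(grid), np.nan)
    for i in range(len(grid)):
        if labels.labels[i] != LABEL_VALID:
            continue
        w = window_samples(bcg, grid, i)
        cardiac = extract_cardiac_component(w, bcg.fs)
        hr[i] = estimate_hr_window(cardiac, bcg.fs, prominence_k=prominence_k)
        resp = extract_respiratory_component(w, bcg.fs)
        rr[i] = estimate_rr_window(resp, bcg.fs, prominence_k=prominence_k)
    hr_valid = np.isfinite(hr) & (hr >= HR_BOUNDS_BPM[0]) & (hr <= HR_BOUNDS_BPM[1])
    rr_valid = np.isfinite(rr) & (rr >= RR_BOUNDS_BRPM[0]) & (rr <= RR_BOUNDS_BRPM[1])
    hr[~hr_valid] = np.nan
    rr[~rr_valid] = np.nan
    return (VitalSeries(grid, hr, hr_valid), VitalSeries(grid, rr, rr_valid))
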