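"""Adaptive AAD-histogram apnea detection.

The detector is unsupervised and per-recording.  Fitting: slice the
derived respiratory signal into 30-s windows with 50% overlap, compute
each window's average absolute deviation (AAD), histogram the AAD values
(equal-width bins over [0, max]), rank bins by count in descending
order, and take the center of the k-th ranked bin (default k = 6) as the
threshold T.  The most populated bins are assumed to be normal
breathing; walking k bins down the ranking lands just outside that bulk.

Detection: slide a 60-s window with 50% overlap (or the 30-s variant),
split it into three equal contiguous subslices, sort their AADs
ascending a1 <= a2 <= a3, and flag the window apneic when
``a3 - a2 > f * T`` (default fraction f = 0.45).  An apneic episode
leaves one subslice dominated by the terminating movement burst (or by
resumed breathing) while its neighbour still holds the quiet spell, so
the top-gap statistic spikes.  Motion artifacts are deliberately NOT
removed first — apneic episodes and their arousals live inside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EventAnnotations, SignalRecord
from .preprocess import WindowGrid, slice_windows, window_samples

__all__ = [
    "ApneaModel",
    "WindowEventSeries",
    "compute_aad",
    "fit_threshold",
    "detect_events",
    "events_to_windows",
    "estimate_ahi",
    "AHI_SEVERITY_CUTPOINTS",
]

#: AHI severity cut-points (events/hour): normal / mild / moderate / severe.
AHI_SEVERITY_CUTPOINTS = (5.0, 15.0, 30.0)


@dataclass
class ApneaModel:
    """Calibrated detector parameters plus the fitted AAD threshold."""

    histogram_index_k: int = 6
    fraction_f: float = 0.45
    n_bins: int = 100
    window_len_s: float = 60.0
    fit_window_s: float = 30.0
    deviation_center: str = "mean"  # or "median"
    aad_threshold_T: float | None = None

    def __post_init__(self) -> None:
        if not (2 <= self.histogram_index_k <= 16):
            raise ValueError("histogram index k must lie in [2, 16]")
        if not (0.2 <= self.fraction_f <= 0.95):
            raise ValueError("fraction f must lie in [0.2, 0.95]")
        if self.n_bins < 2:
            raise ValueError("need at least 2 histogram bins")
        if self.deviation_center not in ("mean", "median"):
            raise ValueError("deviation_center must be 'mean' or 'median'")

    @property
    def subslice_len_s(self) -> float:
        return self.window_len_s / 3.0

    @property
    def hop_s(self) -> float:
        return self.window_len_s / 2.0


@dataclass
class WindowEventSeries:
    """Predicted and reference apneic flags on a half-overlapping grid."""

    grid: WindowGrid
    predicted: np.ndarray
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=bool)
        if self.predicted.size != len(self.grid):
            raise ValueError("predicted length must match the grid")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=bool)
            if self.reference.size != len(self.grid):
                raise ValueError("reference length must match the grid")


def compute_aad(window: np.ndarray, center: str = "mean") -> float:
    """Average absolute deviation of a window about its mean (or median)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("cannot compute AAD of an empty window")
    c = np.mean(window) if center == "mean" else np.median(window)
    return float(np.mean(np.abs(window - c)))


def _window_aads(resp: SignalRecord, window_len_s: float,
                 center: str) -> np.ndarray:
    grid = slice_windows(resp, window_len_s, window_len_s / 2.0)
    return np.array([compute_aad(window_samples(resp, grid, i), center)
                     for i in range(len(grid))])


def ranked_bin_centers(aads: np.ndarray, n_bins: int) -> np.ndarray:
    """Histogram-bin centers ranked by count, descending; stable ties.

    Equal counts keep ascending-AAD order, so ties favour the lower
    (more conservative) threshold.  Only non-empty bins are returned.
    """
    amax = float(np.max(aads))
    if amax <= 0:
        raise ValueError("all AAD values are zero; nothing to threshold")
    counts, edges = np.histogram(aads, bins=n_bins, range=(0.0, amax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort(-counts, kind="stable")
    order = order[counts[order] > 0]
    return centers[order]


def fit_threshold(resp: SignalRecord, model: ApneaModel | None = None,
                  **model_kwargs) -> ApneaModel:
    """Fit the AAD threshold T on a full-recording respiratory signal.

    Motion artifacts must NOT be removed from ``resp`` first; the
    histogram bulk of normal breathing absorbs them.
    """
    if model is None:
        model = ApneaModel(**model_kwargs)
    aads = _window_aads(resp, model.fit_window_s, model.deviation_center)
    ranked = ranked_bin_centers(aads, model.n_bins)
    k = model.histogram_index_k
    if ranked.size < k:
        raise ValueError(
            f"only {ranked.size} non-empty histogram bins; need k={k}"
        )
    model.aad_threshold_T = float(ranked[k - 1])
    return model


def subslice_spread(resp: SignalRecord, grid: WindowGrid,
                    center: str = "mean") -> np.ndarray:
    """Per-window top gap a3 - a2 of the three contiguous subslice AADs."""
    fs = resp.fs
    sub_n = int(round(grid.window_len_s * fs)) // 3
    out = np.empty(len(grid))
    for i, s in enumerate(grid.starts_s):
        i0 = int(round(s * fs))
        aads = sorted(
            compute_aad(resp.samples[i0 + j * sub_n: i0 + (j + 1) * sub_n],
                        center)
            for j in range(3)
        )
        out[i] = aads[2] - aads[1]
    return out


def detect_events(resp: SignalRecord, model: ApneaModel) -> WindowEventSeries:
    """Flag apneic sliding windows with the fitted three-subslice rule."""
    if model.aad_threshold_T is None:
        raise ValueError("model is unfitted: call fit_threshold first")
    grid = slice_windows(resp, model.window_len_s, model.hop_s)
    spread = subslice_spread(resp, grid, model.deviation_center)
    predicted = spread > model.fraction_f * model.aad_threshold_T
    return WindowEventSeries(grid=grid, predicted=predicted)


def events_to_windows(ev: EventAnnotations, grid: WindowGrid,
                      min_overlap_s: float = 10.0) -> np.ndarray:
    """Reference per-window flags: scored event overlap > ``min_overlap_s``.

    A window counts as apneic when a scored event overlaps it by more
    than ``min_overlap_s``.  The default (10 s) is the clinical minimum
    apnea duration: a window merely brushed by an event tail shorter
    than any scorable apnea is not treated as an apneic window.  Pass
    0 for any-overlap labeling.
    """
    ref = np.zeros(len(grid), dtype=bool)
    intervals = ev.intervals()
    for i, s in enumerate(grid.starts_s):
        e = s + grid.window_len_s
        for on, off in intervals:
            if min(off, e) - max(on, s) > min_overlap_s:
                ref[i] = True
                break
    return ref


def estimate_ahi(ev: EventAnnotations) -> tuple[float, str]:
    """Apnea-hypopnea index (events/hour of sleep) and its severity class."""
    if ev.total_sleep_time_s <= 0:
        raise ValueError("total_sleep_time_s must be positive")
    ahi = 3600.0 * len(ev) / ev.total_sleep_time_s
    mild, moderate, severe = AHI_SEVERITY_CUTPOINTS
    if ahi < mild:
        label = "normal"
    elif ahi < moderate:
        label = "mild"
    elif ahi < severe:
        label = "moderate"
    else:
        label = "severe"
    return ahi, label
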