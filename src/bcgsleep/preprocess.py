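"""Overlapping window grid and the SD–MAD artifact / out-of-bed labeling.

The recording is cut into 30-s chunks with 50% overlap.  Each chunk gets
one of three labels from its sample standard deviation (SD):

* ``out_of_bed`` — SD below a fixed floor (default 5 mV): the sensor
  sees essentially nothing, nobody is on the mattress.
* ``motion_artifact`` — SD more than ``multiplier`` (default 4) times
  the median absolute deviation (MAD) of the whole-recording SD array:
  gross body movement swamps the physiological signal.
* ``valid`` — everything in between; only these windows are used for
  vital-sign estimation.

The out-of-bed test takes precedence: a flat window cannot be a motion
artifact.  The MAD is used unscaled (no normal-consistency factor).
Signal coverage is the fraction of recording time not claimed by any
suppressed window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SignalRecord

__all__ = [
    "WindowGrid",
    "WindowLabelSeries",
    "slice_windows",
    "window_samples",
    "label_artifacts",
    "signal_coverage",
    "merge_intervals",
]

LABEL_OUT_OF_BED = "out_of_bed"
LABEL_MOTION = "motion_artifact"
LABEL_VALID = "valid"

_EPS_S = 1e-9


@dataclass
class WindowGrid:
    """A fixed grid of equal-length, typically half-overlapping windows."""

    window_len_s: float
    hop_s: float
    starts_s: np.ndarray

    def __post_init__(self) -> None:
        self.starts_s = np.asarray(self.starts_s, dtype=float)

    def __len__(self) -> int:
        return self.starts_s.size

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.window_len_s


@dataclass
class WindowLabelSeries:
    """Per-window SD values and artifact labels on a grid."""

    grid: WindowGrid
    sd_values: np.ndarray
    labels: np.ndarray  # array of str, one of the three labels
    mad_of_sd: float
    multiplier: float = 4.0
    oob_threshold_mv: float = 5.0

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label


def slice_windows(record: SignalRecord, window_len_s: float = 30.0,
                  hop_s: float | None = None) -> WindowGrid:
    """Build the overlapping window grid; trailing partial windows dropped.

    ``hop_s`` defaults to half the window length (50% overlap).
    """
    if hop_s is None:
        hop_s = window_len_s / 2.0
    if window_len_s <= 0 or hop_s <= 0:
        raise ValueError("window and hop must be positive")
    dur = record.duration_s
    if window_len_s > dur + _EPS_S:
        raise ValueError(
            f"window of {window_len_s} s longer than record ({dur:.3f} s)"
        )
    n_win = int(np.floor((dur - window_len_s) / hop_s + _EPS_S)) + 1
    starts = np.arange(n_win) * hop_s
    return WindowGrid(window_len_s=window_len_s, hop_s=hop_s, starts_s=starts)


def window_samples(record: SignalRecord, grid: WindowGrid, i: int) -> np.ndarray:
    """Samples of the i-th grid window."""
    fs = record.fs
    i0 = int(round(grid.starts_s[i] * fs))
    return record.samples[i0: i0 + int(round(grid.window_len_s * fs))]


def label_artifacts(record: SignalRecord, grid: WindowGrid,
                    multiplier: float = 4.0, oob_threshold_mv: float = 5.0,
                    ddof: int = 1) -> WindowLabelSeries:
    """Label every grid window out-of-bed / motion-artifact / valid.

    The SD of each window is compared first against the out-of-bed floor
    and then against ``multiplier`` times the MAD of the full SD array.
    A degenerate all-identical SD array (MAD = 0) flags nothing as
    motion — by the rule's own logic there are no outliers — and emits
    a warning.
    """
    sds = np.array([np.std(window_samples(record, grid, i), ddof=ddof)
                    for i in range(len(grid))])
    mad = float(np.median(np.abs(sds - np.median(sds))))
    labels = np.full(sds.size, LABEL_VALID, dtype=object)
    oob = sds < oob_threshold_mv
    labels[oob] = LABEL_OUT_OF_BED
    if mad == 0.0:
        warnings.warn(
            "MAD of the window SD array is 0 (identical windows); "
            "no motion artifacts flagged", UserWarning, stacklevel=2,
        )
    else:
        labels[(sds > multiplier * mad) & ~oob] = LABEL_MOTION
    return WindowLabelSeries(
        grid=grid, sd_values=sds, labels=labels.astype(str),
        mad_of_sd=mad, multiplier=multiplier, oob_threshold_mv=oob_threshold_mv,
    )


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Union of possibly overlapping intervals as disjoint sorted spans."""
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def signal_coverage(labels: WindowLabelSeries, record: SignalRecord) -> float:
    """Fraction of the recording not covered by any suppressed window."""
    bad = labels.mask(LABEL_MOTION) | labels.mask(LABEL_OUT_OF_BED)
    spans = merge_intervals(
        (float(s), float(s + labels.grid.window_len_s))
        for s in labels.grid.starts_s[bad]
    )
    dur = record.duration_s
    suppressed = sum(min(b, dur) - max(a, 0.0) for a, b in spans)
    return 1.0 - suppressed / dur
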