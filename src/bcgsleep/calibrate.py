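"""Leave-one-out cross-validated grid search for the detector parameters.

The detector has two free parameters: the histogram rank k (which AAD
histogram bin, counted from the most populated, supplies the threshold
T) and the fraction f of T that the three-subslice top gap must exceed.
Both are chosen by a leave-one-out grid search over a cohort: in each
iteration one subject is held out and every (k, f) cell is scored on the
remaining subjects (threshold fitted per recording, detection on the
same recording, windowed confusion vs the scored events); per-cell,
per-iteration means of sensitivity, specificity and accuracy are
recorded, and the overall cell score is the mean balanced accuracy
across iterations.

Two selection rules for k are provided: ``knee`` — the k at which the
mean sensitivity changes fastest between consecutive ranks (sensitivity
falls and specificity rises with k; the knee marks the crossover) — and
plain ``argmax`` of the overall balanced accuracy.  The fraction is the
argmax of overall balanced accuracy at the chosen k.  Ties break toward
smaller k and smaller f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .apnea import (
    ApneaModel,
    events_to_windows,
    ranked_bin_centers,
    subslice_spread,
    _window_aads,
)
from .io import EventAnnotations, SignalRecord
from .preprocess import slice_windows

__all__ = [
    "CalibrationGrid",
    "DEFAULT_FRACTIONS",
    "DEFAULT_K_VALUES",
    "loocv_grid",
    "select_fraction",
    "select_histogram_index",
]

#: Printed search ranges: fractions 0.20-0.95 step 0.05; ranks 2-16.
DEFAULT_FRACTIONS = np.round(np.arange(0.20, 0.951, 0.05), 2)
DEFAULT_K_VALUES = np.arange(2, 17)


@dataclass
class CalibrationGrid:
    """Full LOOCV grid: per-iteration metric means and overall scores.

    ``per_subject_*`` arrays have shape (n_subjects, n_k, n_fractions);
    ``iteration_*`` arrays (n_iterations, n_k, n_fractions) hold the
    leave-one-out means; ``overall_balanced_accuracy`` (n_k, n_fractions)
    is the mean across iterations.  Confusion counts are kept so every
    derived fraction can be recomputed independently.
    """

    fractions: np.ndarray
    k_values: np.ndarray
    per_subject_counts: np.ndarray  # (n_subj, n_k, n_f, 4) tp, fp, tn, fn
    per_subject_sensitivity: np.ndarray
    per_subject_specificity: np.ndarray
    per_subject_accuracy: np.ndarray
    iteration_sensitivity: np.ndarray
    iteration_specificity: np.ndarray
    iteration_accuracy: np.ndarray
    overall_balanced_accuracy: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.per_subject_counts.shape[0]


def _subject_cells(resp: SignalRecord, ev: EventAnnotations,
                   k_values: np.ndarray, fractions: np.ndarray,
                   window_len_s: float, n_bins: int,
                   center: str) -> np.ndarray:
    """Confusion counts (n_k, n_f, 4) for one subject at every cell.

    The AAD spread per window and the ranked histogram are independent
    of (k, f), so they are computed once and every cell reduces to a
    vectorised threshold comparison.
    """
    probe = ApneaModel(window_len_s=window_len_s, n_bins=n_bins,
                       deviation_center=center)
    aads = _window_aads(resp, probe.fit_window_s, center)
    ranked = ranked_bin_centers(aads, n_bins)
    if ranked.size < k_values.max():
        raise ValueError(
            f"only {ranked.size} non-empty histogram bins; the grid "
            f"needs k up to {k_values.max()}"
        )
    grid = slice_windows(resp, window_len_s, window_len_s / 2.0)
    spread = subslice_spread(resp, grid, center)
    ref = events_to_windows(ev, grid)
    counts = np.empty((k_values.size, fractions.size, 4), dtype=float)
    for i, k in enumerate(k_values):
        t_k = ranked[k - 1]
        for j, f in enumerate(fractions):
            pred = spread > f * t_k
            counts[i, j] = (
                np.sum(pred & ref), np.sum(pred & ~ref),
                np.sum(~pred & ~ref), np.sum(~pred & ref),
            )
    return counts


def loocv_grid(cohort: list[tuple[SignalRecord, EventAnnotations]],
               fractions: np.ndarray | None = None,
               k_values: np.ndarray | None = None,
               window_len_s: float = 60.0, n_bins: int = 100,
               deviation_center: str = "mean") -> CalibrationGrid:
    """Evaluate every (k, f) cell under leave-one-out cross-validation.

    ``cohort`` is a list of (respiratory signal, scored events) pairs.
    Per-iteration means are unweighted across included subjects; windows
    with an undefined sensitivity or specificity (single-class
    reference) propagate as NaN and are excluded by nan-mean.
    """
    if len(cohort) < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    fr = DEFAULT_FRACTIONS if fractions is None else np.asarray(fractions, float)
    kv = DEFAULT_K_VALUES if k_values is None else np.asarray(k_values, int)
    n = len(cohort)

    counts = np.stack([
        _subject_cells(resp, ev, kv, fr, window_len_s, n_bins, deviation_center)
        for resp, ev in cohort
    ])  # (n, n_k, n_f, 4)
    tp, fp, tn, fn = (counts[..., i] for i in range(4))
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    acc = (tp + tn) / counts[..., :4].sum(axis=-1)
    bal = 0.5 * (sens + spec)

    def _loo_mean(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        for i in range(n):
            idx = [j for j in range(n) if j != i]
            out[i] = np.nanmean(x[idx], axis=0)
        return out

    it_sens, it_spec, it_acc = map(_loo_mean, (sens, spec, acc))
    overall = np.nanmean(_loo_mean(bal), axis=0)
    return CalibrationGrid(
        fractions=fr, k_values=kv,
        per_subject_counts=counts,
        per_subject_sensitivity=sens, per_subject_specificity=spec,
        per_subject_accuracy=acc,
        iteration_sensitivity=it_sens, iteration_specificity=it_spec,
        iteration_accuracy=it_acc,
        overall_balanced_accuracy=overall,
    )


def select_fraction(grid: CalibrationGrid, k: int) -> float:
    """Fraction maximising overall balanced accuracy at fixed k.

    Ties break toward the smaller fraction.
    """
    ki = int(np.nonzero(grid.k_values == k)[0][0])
    row = grid.overall_balanced_accuracy[ki]
    return float(grid.fractions[int(np.argmax(row))])


def select_histogram_index(grid: CalibrationGrid,
                           strategy: str = "knee") -> int:
    """Select the histogram rank k.

    ``knee``: the k with the largest absolute change in mean sensitivity
    to the next rank (averaged over fractions and iterations); ties go
    to the smallest k.  ``argmax``: the k whose mean overall balanced
    accuracy across fractions is highest.
    """
    if strategy == "knee":
        s_k = np.nanmean(grid.iteration_sensitivity, axis=(0, 2))
        deltas = np.abs(np.diff(s_k))
        return int(grid.k_values[int(np.argmax(deltas))])
    if strategy == "argmax":
        score = np.nanmean(grid.overall_balanced_accuracy, axis=1)
        return int(grid.k_values[int(np.argmax(score))])
    raise ValueError(f"unknown strategy {strategy!r}")
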