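"""Evaluation statistics: windowed confusion metrics and device agreement.

Confusion metrics compare predicted vs reference per-window apneic
flags; the association P value is a two-tailed chi-square test of
independence on the 2x2 table, falling back to Fisher's exact test when
any expected cell is below 5.

Agreement between estimated and reference rate series uses NMAE, NRMSE
and MAPE (percent), Bland-Altman limits of agreement (mean difference
+/- 1.96 sample SD) and Pearson correlation, restricted to windows valid
in both series.  NMAE/NRMSE are normalised by the mean of the reference
series, which makes NMAE coincide with MAPE for a constant reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .vitals import VitalSeries

__all__ = [
    "ConfusionSummary",
    "AgreementReport",
    "confusion_metrics",
    "agreement_errors",
    "summarize_cohort",
]


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    p_value: float


@dataclass
class AgreementReport:
    nmae_pct: float
    nrmse_pct: float
    mape_pct: float
    loa_lower: float
    loa_upper: float
    sd_of_difference: float
    mean_difference: float
    pearson_r: float
    r_p_value: float
    n_pairs: int


def confusion_metrics(pred, ref) -> ConfusionSummary:
    """Counts and derived fractions for predicted vs reference flags."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.size == 0 or pred.size != ref.size:
        raise ValueError("pred and ref must be equal-length and non-empty")
    tp = int(np.sum(pred & ref))
    fp = int(np.sum(pred & ~ref))
    tn = int(np.sum(~pred & ~ref))
    fn = int(np.sum(~pred & ref))
    if tp + fn == 0:
        warnings.warn("no reference positives: sensitivity undefined",
                      UserWarning, stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no reference negatives: specificity undefined",
                      UserWarning, stacklevel=2)
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    acc = (tp + tn) / pred.size
    bal = (sens + spec) / 2.0
    p = _association_p(tp, fn, fp, tn)
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                            specificity=spec, accuracy=acc,
                            balanced_accuracy=bal, p_value=p)


def _association_p(tp: int, fn: int, fp: int, tn: int) -> float:
    table = np.array([[tp, fn], [fp, tn]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan")
    expected = stats.contingency.expected_freq(table)
    if expected.min() < 5:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(stats.chi2_contingency(table, correction=False)[1])


def _pair(est, ref):
    if isinstance(est, VitalSeries):
        if not isinstance(ref, VitalSeries):
            raise TypeError("est and ref must both be VitalSeries or arrays")
        if len(est.grid) != len(ref.grid) or not np.allclose(
                est.grid.starts_s, ref.grid.starts_s):
            raise ValueError("series are on different grids")
        mask = est.valid_mask & ref.valid_mask
        return est.values[mask], ref.values[mask]
    e = np.asarray(est, dtype=float)
    r = np.asarray(ref, dtype=float)
    if e.size != r.size:
        raise ValueError("series lengths differ")
    mask = np.isfinite(e) & np.isfinite(r)
    return e[mask], r[mask]


def agreement_errors(est, ref) -> AgreementReport:
    """Paired-series agreement between estimated and reference rates.

    Accepts two :class:`~bcgsleep.vitals.VitalSeries` on the same grid,
    or two plain arrays (NaN marks invalid windows).
    """
    e, r = _pair(est, ref)
    if e.size < 2:
        raise ValueError("need at least 2 mutually valid pairs")
    diff = e - r
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    denom = float(np.mean(r))
    if denom == 0:
        raise ValueError("reference mean is zero; cannot normalise")
    nonzero = r != 0
    if not np.all(nonzero):
        warnings.warn("zero reference values excluded from MAPE",
                      UserWarning, stacklevel=2)
    mape = float(100.0 * np.mean(np.abs(diff[nonzero]) / r[nonzero]))
    md = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.all(e == e[0]) or np.all(r == r[0]):
        r_val, r_p = float("nan"), float("nan")
    else:
        r_val, r_p = stats.pearsonr(e, r)
    return AgreementReport(
        nmae_pct=100.0 * mae / denom,
        nrmse_pct=100.0 * rmse / denom,
        mape_pct=mape,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
        sd_of_difference=sd,
        mean_difference=md,
        pearson_r=float(r_val),
        r_p_value=float(r_p),
        n_pairs=int(e.size),
    )


def summarize_cohort(reports: list) -> dict[str, tuple[float, float]]:
    """Unweighted mean and sample SD of every numeric metric across subjects."""
    if not reports:
        raise ValueError("need at least one report")
    out: dict[str, tuple[float, float]] = {}
    first = reports[0]
    for name in vars(first):
        vals = np.array([float(getattr(rep, name)) for rep in reports])
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
        out[name] = (mean, sd)
    return out
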