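"""Seeded synthetic bed-sensor recordings with aligned references and truth.

The generator emulates the structure a bed-embedded pressure (BCG) sensor
sees at 50 Hz: a dominant respiratory oscillation, a much smaller cardiac
beat train riding on it, additive sensor noise, and three kinds of
disturbance — apneic episodes (respiratory amplitude collapses for at
least 10 s and the episode terminates in a gross-movement arousal burst),
spontaneous motion-artifact bursts, and near-flat out-of-bed stretches.
Aligned reference channels (impulse-like ECG R-peaks, thoracic-effort
equal to the respiratory component) and ground-truth beat/breath times
and event annotations are returned for evaluation.

Amplitudes are millivolts throughout, so the 5 mV out-of-bed threshold
used by the artifact-labeling stage applies literally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import EventAnnotations, SignalRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RecordingBundle",
    "simulate_recording",
    "simulate_cohort",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic overnight recording.

    Rates are means with per-interval Gaussian jitter (``*_sd``) truncated
    at ±20% of the mean period.  ``apnea_rate_per_hr`` is the target
    event density, i.e. the true AHI of the recording.  The arousal burst
    occupies the final ``arousal_burst_s`` seconds of each scored event
    (the movement that terminates the apnea), so the breathing pause
    itself lasts ``duration − arousal_burst_s`` seconds; the minimum
    event duration must keep that pause at or above the 10 s clinical
    floor.
    """

    duration_s: float = 600.0
    fs: float = 50.0
    hr_bpm: float = 65.0
    hr_sd_bpm: float = 2.0
    rr_brpm: float = 15.0
    rr_sd_brpm: float = 0.5
    resp_amp_mv: float = 150.0
    cardiac_amp_mv: float = 50.0
    noise_sd_mv: float = 3.0
    amp_log_sd: float = 0.6
    amp_corr_time_s: float = 120.0
    apnea_rate_per_hr: float = 0.0
    apnea_duration_s: tuple[float, float] = (15.0, 20.0)
    apnea_amp_drop_frac: float = 0.85
    arousal_burst_amp: float = 10.0  # noise SD as a multiple of resp_amp_mv
    arousal_burst_s: float = 5.0
    apnea_min_spacing_s: float = 30.0  # minimum onset-to-onset spacing
    motion_rate_per_hr: float = 0.0
    motion_burst_amp: float = 10.0
    motion_duration_s: tuple[float, float] = (2.0, 5.0)
    out_of_bed_segments: tuple[tuple[float, float], ...] = ()
    out_of_bed_noise_sd_mv: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.fs > 0 and self.duration_s > 0):
            raise ValueError("fs and duration_s must be positive")
        for name in (
            "resp_amp_mv", "cardiac_amp_mv", "noise_sd_mv",
            "arousal_burst_amp", "motion_burst_amp", "out_of_bed_noise_sd_mv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.apnea_duration_s[0] < 10.0:
            raise ValueError("minimum apnea duration must be >= 10 s")
        if self.apnea_duration_s[0] > self.apnea_duration_s[1]:
            raise ValueError("apnea_duration_s must be (min, max) with min <= max")
        if self.apnea_duration_s[0] - self.arousal_burst_s < 0:
            raise ValueError("arousal burst longer than the shortest event")
        if not (0.0 <= self.apnea_amp_drop_frac <= 1.0):
            raise ValueError("apnea_amp_drop_frac must lie in [0, 1]")
        segs = sorted((float(a), float(b)) for a, b in self.out_of_bed_segments)
        for a, b in segs:
            if not (0.0 <= a < b <= self.duration_s):
                raise ValueError(f"out-of-bed segment ({a}, {b}) outside recording")
        for (a0, b0), (a1, b1) in zip(segs, segs[1:]):
            if a1 < b0:
                raise ValueError("out-of-bed segments overlap")

    @classmethod
    def apnea_oracle_regime(cls, duration_s: float = 14400.0, seed: int = 0,
                            **overrides) -> "SimulationConfig":
        """Idealised detection-power conditions for the apnea detector.

        Severe-OSA-like event density with the default >= 70% amplitude
        drop and strong arousal bursts, a stable respiratory amplitude
        and no spontaneous motion, so the clean and apneic AAD
        distributions separate by well over 5x.  This is the regime in
        which the three-subslice rule is expected to work; realistic
        overnight amplitude drift (the default ``amp_log_sd``) erodes it.
        """
        params = dict(duration_s=duration_s, amp_log_sd=0.10,
                      apnea_rate_per_hr=20.0, apnea_duration_s=(22.0, 26.0),
                      arousal_burst_s=12.0, arousal_burst_amp=20.0,
                      apnea_min_spacing_s=60.0, motion_rate_per_hr=0.0,
                      seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruth:
    """Truth channel for one recording: what the generator actually placed."""

    beat_times_s: np.ndarray
    breath_times_s: np.ndarray
    apnea_events: EventAnnotations
    motion_intervals_s: list[tuple[float, float]]
    out_of_bed_intervals_s: list[tuple[float, float]]


@dataclass
class RecordingBundle:
    subject_id: str
    config: SimulationConfig
    bcg: SignalRecord
    ecg: SignalRecord
    effort: SignalRecord
    truth: GroundTruth


def _ou_process(rng, n: int, fs: float, sd: float, tau: float) -> np.ndarray:
    """Slow mean-reverting drift (OU) with stationary SD ``sd``, at 1 Hz.

    Models the gradual overnight change in sensor coupling and breathing
    depth; the 30-s window SD distribution it induces is wide enough for
    the SD-vs-MAD artifact rule to behave as it does on real recordings.
    """
    if sd == 0:
        return np.zeros(n)
    n_coarse = int(np.ceil(n / fs)) + 2
    a = np.exp(-1.0 / tau)
    innov = rng.normal(0.0, sd * np.sqrt(1 - a * a), size=n_coarse)
    x = np.empty(n_coarse)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n_coarse):
        x[i] = a * x[i - 1] + innov[i]
    t_coarse = np.arange(n_coarse, dtype=float)
    return np.interp(np.arange(n) / fs, t_coarse, x)


def _movement_burst(rng, m: int, fs: float, sd: float) -> np.ndarray:
    """Gross-body-movement noise: low-frequency dominated, target SD.

    Movements shift the whole pressure baseline, so most burst power
    sits below ~1.5 Hz — inside the respiratory band, where the apnea
    detector sees it.
    """
    if m == 0:
        return np.zeros(0)
    from scipy.signal import butter, sosfiltfilt

    white = rng.normal(0.0, 1.0, size=m)
    if m > 30:
        sos = butter(2, min(1.5, 0.45 * fs), btype="lowpass", fs=fs,
                     output="sos")
        white = sosfiltfilt(sos, white)
    scale = np.std(white)
    if scale > 0:
        white = sd * white / scale
    # crescendo/decay envelope: movements build up and die away
    return white * np.hanning(m) * np.sqrt(8.0 / 3.0)


def _jittered_times(rng, mean_period: float, sd_period: float,
                    duration: float) -> np.ndarray:
    """Cumulative event times with truncated per-interval Gaussian jitter."""
    n_max = int(duration / (0.8 * mean_period)) + 2
    periods = rng.normal(mean_period, sd_period, size=n_max)
    periods = np.clip(periods, 0.8 * mean_period, 1.2 * mean_period)
    times = np.cumsum(periods)
    return times[times < duration]


def _complement(intervals: Sequence[tuple[float, float]],
                lo: float, hi: float) -> list[tuple[float, float]]:
    """Sorted complement of ``intervals`` within [lo, hi]."""
    out, cursor = [], lo
    for a, b in sorted(intervals):
        if a > cursor:
            out.append((cursor, min(a, hi)))
        cursor = max(cursor, b)
    if cursor < hi:
        out.append((cursor, hi))
    return [(a, b) for a, b in out if b - a > 0]


def _place_with_min_spacing(rng, n: int, seg_lo: float, seg_hi: float,
                            spacing: float) -> np.ndarray:
    """n onset times in [seg_lo, seg_hi] with pairwise spacing >= spacing.

    Uses the classic order-statistics construction: sample n points
    uniformly in the interval shortened by the total spacing budget,
    sort, then shift the i-th point by i*spacing.
    """
    slack = (seg_hi - seg_lo) - (n - 1) * spacing
    if n == 1:
        return np.array([rng.uniform(seg_lo, seg_hi)])
    if slack < 0:
        raise ValueError(
            f"cannot place {n} events with {spacing:.0f}s spacing in "
            f"{seg_hi - seg_lo:.0f}s"
        )
    base = np.sort(rng.uniform(0.0, slack, size=n))
    return seg_lo + base + spacing * np.arange(n)


def _place_events(rng, n_events: int, free: list[tuple[float, float]],
                  spacing: float, max_len: float) -> list[float]:
    """Distribute event onsets over free segments, spacing-constrained."""
    usable = [(a, b - max_len) for a, b in free if b - a > max_len]
    if not usable and n_events > 0:
        raise ValueError("no room to place events outside excluded intervals")
    # capacity per segment under the spacing constraint
    caps = [int((b - a) // spacing) + 1 for a, b in usable]
    lengths = np.array([b - a for a, b in usable], dtype=float)
    onsets: list[float] = []
    remaining = n_events
    # allocate proportionally to usable length, clipped by capacity
    alloc = [0] * len(usable)
    if n_events > 0:
        ideal = lengths / lengths.sum() * n_events
        alloc = [min(int(round(x)), c) for x, c in zip(ideal, caps)]
        # fix rounding drift
        while sum(alloc) < n_events:
            room = [c - a for a, c in zip(alloc, caps)]
            if max(room) <= 0:
                raise ValueError(
                    f"cannot place {n_events} events: capacity "
                    f"{sum(caps)} under the spacing constraint"
                )
            alloc[int(np.argmax(room))] += 1
        while sum(alloc) > n_events:
            alloc[int(np.argmax(alloc))] -= 1
    for (a, b), k in zip(usable, alloc):
        if k > 0:
            onsets.extend(_place_with_min_spacing(rng, k, a, b, spacing))
        remaining -= k
    return sorted(onsets)


def _add_pulses(samples: np.ndarray, fs: float, times: np.ndarray,
                shape, half_width: float, amplitude: float) -> None:
    """Add ``amplitude * shape(t - t_k)`` around each pulse time in place."""
    n = samples.size
    for tk in times:
        i0 = max(0, int(np.ceil((tk - half_width) * fs)))
        i1 = min(n, int(np.floor((tk + half_width) * fs)) + 1)
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / fs - tk
        samples[i0:i1] += amplitude * shape(t_rel)


def _beat_template(t: np.ndarray) -> np.ndarray:
    """BCG beat complex: a ~4 Hz damped oscillation plus a slow J-wave hump.

    The hump carries the sub-1.5 Hz energy that survives the level-4
    wavelet smooth, which is what makes each beat a detectable local
    maximum there; the oscillation supplies the fast I-J-K detail seen in
    raw recordings.  Normalised to unit peak.
    """
    osc = np.exp(-(t ** 2) / (2 * 0.08 ** 2)) * np.cos(2 * np.pi * 4.0 * t)
    hump = np.exp(-(t ** 2) / (2 * 0.15 ** 2))
    w = 0.35 * osc + hump
    return w / 1.35


def _r_wave(t: np.ndarray) -> np.ndarray:
    """Impulse-like ECG R-peak (narrow Gaussian)."""
    return np.exp(-(t ** 2) / (2 * 0.018 ** 2))


def simulate_recording(
    cfg: SimulationConfig,
) -> tuple[SignalRecord, SignalRecord, SignalRecord, GroundTruth]:
    """Generate one recording: (bcg, ecg, effort, truth).

    Identical configs (including ``seed``) produce bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs, dur = cfg.fs, cfg.duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    oob = [(float(a), float(b)) for a, b in sorted(cfg.out_of_bed_segments)]
    in_bed = _complement(oob, 0.0, dur)
    in_bed_s = sum(b - a for a, b in in_bed)

    # ---- apneic episodes -------------------------------------------------
    n_ev = int(round(cfg.apnea_rate_per_hr * in_bed_s / 3600.0))
    max_dur = cfg.apnea_duration_s[1]
    spacing = max(cfg.apnea_min_spacing_s, max_dur + 1.0)
    onsets = _place_events(rng, n_ev, in_bed, spacing, max_dur) if n_ev else []
    durations = rng.uniform(*cfg.apnea_duration_s, size=len(onsets))
    etypes = rng.choice(
        ["obstructive_apnea", "hypopnea", "central_apnea", "mixed_apnea"],
        size=len(onsets), p=[0.55, 0.35, 0.05, 0.05],
    )
    events = EventAnnotations(
        events=[(float(o), float(d), str(e))
                for o, d, e in zip(onsets, durations, etypes)],
        total_sleep_time_s=in_bed_s,
    )
    apnea_iv = events.intervals()
    burst_iv = [(b - cfg.arousal_burst_s, b) for _, b in apnea_iv]

    # ---- spontaneous motion bursts ---------------------------------------
    n_mo = int(round(cfg.motion_rate_per_hr * in_bed_s / 3600.0))
    motion_iv: list[tuple[float, float]] = []
    if n_mo:
        pad = 2.0
        excluded = oob + [(a - pad, b + pad) for a, b in apnea_iv]
        free = _complement(excluded, 0.0, dur)
        mo_max = cfg.motion_duration_s[1]
        mo_on = _place_events(rng, n_mo, free, cfg.apnea_min_spacing_s, mo_max)
        mo_dur = rng.uniform(*cfg.motion_duration_s, size=len(mo_on))
        motion_iv = [(float(a), float(a + d)) for a, d in zip(mo_on, mo_dur)]

    # ---- respiration ------------------------------------------------------
    mean_bp = 60.0 / cfg.rr_brpm
    rates = cfg.rr_brpm + rng.normal(0.0, cfg.rr_sd_brpm,
                                     size=int(dur / (0.8 * mean_bp)) + 2)
    periods = np.clip(60.0 / rates, 0.8 * mean_bp, 1.2 * mean_bp)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    # piecewise-linear breathing phase; one cycle per period
    phase = np.interp(t, bounds, np.arange(bounds.size, dtype=float))
    breathing = np.sin(2 * np.pi * phase)
    breath_times = bounds[:-1] + 0.25 * periods  # inhalation peaks
    breath_times = breath_times[breath_times < dur]

    envelope = cfg.resp_amp_mv * np.exp(
        _ou_process(rng, n, fs, cfg.amp_log_sd, cfg.amp_corr_time_s)
    )
    reduction = np.ones(n)
    for a, b in apnea_iv:
        i0, i1 = int(a * fs), min(n, int(np.ceil(b * fs)))
        reduction[i0:i1] = 1.0 - cfg.apnea_amp_drop_frac
    resp = envelope * reduction * breathing

    # ---- cardiac beat train ----------------------------------------------
    mean_hp = 60.0 / cfg.hr_bpm
    beat_times = _jittered_times(rng, mean_hp, mean_hp * cfg.hr_sd_bpm / cfg.hr_bpm,
                                 dur)
    oob_mask_t = np.zeros(beat_times.size, dtype=bool)
    for a, b in oob:
        oob_mask_t |= (beat_times >= a) & (beat_times < b)
    beat_times = beat_times[~oob_mask_t]
    breath_in_bed = np.ones(breath_times.size, dtype=bool)
    for a, b in oob:
        breath_in_bed &= ~((breath_times >= a) & (breath_times < b))
    breath_times = breath_times[breath_in_bed]

    cardiac = np.zeros(n)
    _add_pulses(cardiac, fs, beat_times, _beat_template, 0.35, cfg.cardiac_amp_mv)

    # ---- assemble the BCG -------------------------------------------------
    bcg = resp + cardiac + rng.normal(0.0, cfg.noise_sd_mv, size=n)
    for a, b in burst_iv + motion_iv:
        i0, i1 = max(0, int(a * fs)), min(n, int(np.ceil(b * fs)))
        amp = cfg.arousal_burst_amp if (a, b) in burst_iv else cfg.motion_burst_amp
        bcg[i0:i1] += _movement_burst(rng, i1 - i0, fs, amp * cfg.resp_amp_mv)
    for a, b in oob:
        i0, i1 = max(0, int(a * fs)), min(n, int(np.ceil(b * fs)))
        bcg[i0:i1] = rng.normal(0.0, cfg.out_of_bed_noise_sd_mv, size=i1 - i0)
        resp[i0:i1] = 0.0

    # ---- references -------------------------------------------------------
    ecg = rng.normal(0.0, 0.01, size=n)
    _add_pulses(ecg, fs, beat_times, _r_wave, 0.08, 1.0)

    truth = GroundTruth(
        beat_times_s=beat_times,
        breath_times_s=breath_times,
        apnea_events=events,
        motion_intervals_s=motion_iv,
        out_of_bed_intervals_s=oob,
    )
    mk = lambda x, name: SignalRecord(samples=x, fs=fs, channel_name=name)
    return mk(bcg, "bcg"), mk(ecg, "ecg"), mk(resp.copy(), "effort"), truth


def simulate_cohort(
    n_subjects: int,
    base_cfg: SimulationConfig | None = None,
    ahi_targets: Sequence[float] | None = None,
    overrides: Sequence[dict] | None = None,
    seed: int = 0,
) -> list[RecordingBundle]:
    """Generate a reproducible cohort spanning a range of severities.

    ``ahi_targets`` defaults to an even spread over 5–90 events/hour,
    mirroring the severity spread of a clinical OSA cohort.  Per-subject
    seeds are derived deterministically from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    base = base_cfg if base_cfg is not None else SimulationConfig(duration_s=3600.0)
    if ahi_targets is None:
        ahi_targets = np.linspace(5.0, 90.0, n_subjects)
    if len(ahi_targets) != n_subjects:
        raise ValueError("ahi_targets length must equal n_subjects")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2 ** 31)
    bundles = []
    for i in range(n_subjects):
        changes = {"apnea_rate_per_hr": float(ahi_targets[i]),
                   "seed": int(child_seeds[i])}
        if overrides is not None and overrides[i]:
            changes.update(overrides[i])
        cfg = replace(base, **changes)
        bcg, ecg, effort, truth = simulate_recording(cfg)
        sid = f"S{i + 1:02d}"
        for rec in (bcg, ecg, effort):
            rec.subject_id = sid
        bundles.append(RecordingBundle(sid, cfg, bcg, ecg, effort, truth))
    return bundles
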