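"""Reading and writing signals and scored-event annotations.

The canonical on-disk formats are plain text:

* **Signal CSV** — optional ``#``-prefixed header lines carrying ``fs``,
  ``channel`` and ``subject`` metadata, followed by either a single value
  column (millivolts) or two columns ``time_s,value_mV``.  When a time
  column is present the sampling must be uniform; the rate is derived
  from the time step.
* **Annotation CSV** — header ``onset_s,duration_s,type`` with one scored
  respiratory event per row.  Event types are restricted to the four
  classes used in clinical sleep scoring: obstructive apnea, hypopnea,
  central apnea and mixed apnea.

Annotation times are seconds from recording start; events occupy the
half-open interval ``[onset, onset + duration)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EVENT_TYPES",
    "SignalRecord",
    "EventAnnotations",
    "SignalFormatError",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
]

#: Scored-event classes recognised by the pipeline.
EVENT_TYPES = ("obstructive_apnea", "hypopnea", "central_apnea", "mixed_apnea")

#: Tolerance (seconds) for uniform-sampling verification of a time column.
_UNIFORM_TOL_S = 1e-6


class SignalFormatError(ValueError):
    """Raised when a signal or annotation file violates the expected format."""


@dataclass
class SignalRecord:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    samples
        Signal amplitudes in millivolts.
    fs
        Sampling rate in Hz (default 50, the bed-sensor rate).
    channel_name, subject_id
        Free-text metadata.
    start_time
        Offset of the first sample from the recording origin, seconds.
    """

    samples: np.ndarray
    fs: float = 50.0
    channel_name: str = ""
    subject_id: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        """Recording length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the recording origin."""
        return self.start_time + np.arange(self.samples.size) / self.fs

    def copy_with(self, **changes) -> "SignalRecord":
        return replace(self, **changes)


@dataclass
class EventAnnotations:
    """Scored respiratory events with the total sleep time they refer to.

    ``events`` is a list of ``(onset_s, duration_s, type)`` tuples; types
    must be members of :data:`EVENT_TYPES`.  With ``strict=True`` events
    shorter than the 10-s clinical minimum raise; otherwise they warn.
    """

    events: list[tuple[float, float, str]] = field(default_factory=list)
    total_sleep_time_s: float = 0.0
    strict: bool = False

    def __post_init__(self) -> None:
        checked = []
        for onset, duration, etype in self.events:
            onset, duration = float(onset), float(duration)
            if etype not in EVENT_TYPES:
                raise ValueError(
                    f"unknown event type {etype!r}; expected one of {EVENT_TYPES}"
                )
            if onset < 0:
                raise ValueError(f"event onset must be non-negative, got {onset}")
            if duration < 10.0:
                msg = f"event at {onset:.1f}s lasts {duration:.1f}s (< 10 s minimum)"
                if self.strict:
                    raise ValueError(msg)
                warnings.warn(msg, UserWarning, stacklevel=2)
            checked.append((onset, duration, etype))
        self.events = checked

    def __len__(self) -> int:
        return len(self.events)

    def intervals(self) -> list[tuple[float, float]]:
        """Half-open event intervals ``[onset, onset + duration)``."""
        return [(o, o + d) for o, d, _ in self.events]


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip().lower()] = value.strip()
    return meta


def read_signal(path: str | Path) -> SignalRecord:
    """Read a signal CSV into a :class:`SignalRecord`.

    Accepts either a single value column with an ``fs`` header line, or
    two columns ``time_s,value_mV`` from which the rate is derived after
    verifying uniform sampling to within 1 microsecond.
    """
    path = Path(path)
    header_lines: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line)
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SignalFormatError(
                    f"{path}: non-numeric row at line {lineno}: {line!r}"
                ) from exc
    if not rows:
        raise SignalFormatError(f"{path}: no numeric data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise SignalFormatError(f"{path}: inconsistent column counts {sorted(widths)}")
    data = np.asarray(rows, dtype=float)
    meta = _parse_header(header_lines)

    if data.shape[1] == 1:
        if "fs" not in meta:
            raise SignalFormatError(
                f"{path}: single-column file requires an '# fs=<Hz>' header line"
            )
        fs = float(meta["fs"])
        samples = data[:, 0]
        start = float(meta.get("start_time", 0.0))
    elif data.shape[1] == 2:
        t, samples = data[:, 0], data[:, 1]
        if t.size < 2:
            raise SignalFormatError(f"{path}: time column needs at least 2 rows")
        steps = np.diff(t)
        if np.any(np.abs(steps - steps[0]) > _UNIFORM_TOL_S) or steps[0] <= 0:
            raise SignalFormatError(
                f"{path}: time column is not uniformly sampled "
                f"(steps range {steps.min():.6g}..{steps.max():.6g} s)"
            )
        fs = 1.0 / steps[0]
        start = float(t[0])
    else:
        raise SignalFormatError(
            f"{path}: expected 1 or 2 columns, found {data.shape[1]}"
        )

    return SignalRecord(
        samples=samples,
        fs=fs,
        channel_name=meta.get("channel", ""),
        subject_id=meta.get("subject", ""),
        start_time=start,
    )


def write_signal(record: SignalRecord, path: str | Path) -> Path:
    """Write a :class:`SignalRecord` to a signal CSV (value column + header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={float(record.fs)!r}\n")
        if record.channel_name:
            fh.write(f"# channel={record.channel_name}\n")
        if record.subject_id:
            fh.write(f"# subject={record.subject_id}\n")
        if record.start_time:
            fh.write(f"# start_time={float(record.start_time)!r}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")
    return path


def read_annotations(path: str | Path, strict: bool = False) -> EventAnnotations:
    """Read a scored-event annotation CSV."""
    path = Path(path)
    events: list[tuple[float, float, str]] = []
    tst = 0.0
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    header_meta = _parse_header([ln for ln in lines if ln.startswith("#")])
    tst = float(header_meta.get("total_sleep_time_s", 0.0))
    body = [ln for ln in lines if not ln.startswith("#")]
    if not body or body[0].replace(" ", "") != "onset_s,duration_s,type":
        raise SignalFormatError(
            f"{path}: expected header 'onset_s,duration_s,type'"
        )
    for lineno, line in enumerate(body[1:], start=2):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise SignalFormatError(f"{path}: malformed row at line {lineno}: {line!r}")
        try:
            onset, duration = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise SignalFormatError(
                f"{path}: non-numeric onset/duration at line {lineno}"
            ) from exc
        events.append((onset, duration, parts[2]))
    return EventAnnotations(events=events, total_sleep_time_s=tst, strict=strict)


def write_annotations(annotations: EventAnnotations, path: str | Path) -> Path:
    """Write annotations to CSV; round-trips through :func:`read_annotations`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# total_sleep_time_s={float(annotations.total_sleep_time_s)!r}\n")
        fh.write("onset_s,duration_s,type\n")
        for onset, duration, etype in annotations.events:
            fh.write(f"{float(onset)!r},{float(duration)!r},{etype}\n")
    return path
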