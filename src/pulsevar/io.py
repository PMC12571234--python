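"""Waveform containers, delimited-text I/O, and phase/window segmentation.

Arterial pressure recordings are exchanged as plain delimited text: either
two columns ``time_s, pressure_mmHg`` or a single pressure column with the
sampling rate carried in ``#``-prefixed header lines.  Recordings are cut
into the protocol's 15-minute phases (baseline / hemorrhage / recovery) and
each phase into three 5-minute analysis windows labelled by the minute at
which the window ends (5, 10, ..., 45).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PhaseSchedule

__all__ = [
    "PressureWaveform",
    "WindowSet",
    "read_waveform",
    "write_waveform",
    "segment_windows",
]


@dataclass
class PressureWaveform:
    """Uniformly sampled arterial pressure trace.

    Parameters
    ----------
    samples : ndarray
        Pressure in mmHg.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds.
    subject_id : str
        Free-form subject identifier.
    phase_label : str, optional
        Protocol phase this trace belongs to, if it is a segment.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    subject_id: str = ""
    phase_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Recording length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class WindowSet:
    """5-minute analysis windows keyed by group label (end minute).

    ``windows`` maps label -> waveform segment; ``phases`` maps label -> the
    protocol phase the window belongs to.
    """

    windows: dict = field(default_factory=dict)
    phases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.windows) != set(self.phases):
            raise ValueError("windows and phases must share the same labels")

    @property
    def labels(self) -> list:
        return sorted(self.windows)

    def __iter__(self):
        for label in self.labels:
            yield label, self.windows[label], self.phases[label]

    def __len__(self) -> int:
        return len(self.windows)


_HEADER_RE = re.compile(r"#\s*([A-Za-z0-9_]+)\s*[=:]\s*(.+?)\s*$")


def _parse_header(path: Path) -> tuple[dict, int]:
    """Collect ``# key = value`` header lines; return (mapping, n_header_lines)."""
    meta: dict = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            m = _HEADER_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
    return meta, n


def read_waveform(path, fs_override: Optional[float] = None) -> PressureWaveform:
    """Read a pressure waveform from delimited text.

    Two-column files (``time_s, pressure``) have their sampling rate inferred
    from the median time step and checked for uniformity to 1 part in 1e3.
    One-column files require ``fs`` from an ``# fs_hz = ...`` header line or
    from ``fs_override`` (which always wins when given).

    Raises
    ------
    ValueError
        If timestamps are non-uniform beyond tolerance (the first offending
        gap is named) or no sampling rate is available.
    """
    path = Path(path)
    meta, skip = _parse_header(path)
    data = np.loadtxt(path, delimiter=_sniff_delimiter(path, skip), skiprows=skip, ndmin=2)
    if data.shape[1] not in (1, 2):
        raise ValueError(f"expected 1 or 2 columns, found {data.shape[1]} in {path}")

    subject_id = meta.get("subject_id", "")
    phase_label = meta.get("phase_label") or None

    if data.shape[1] == 2:
        t, x = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError("two-column file needs at least 2 samples to infer fs")
        step = float(np.median(dt))
        if step <= 0:
            raise ValueError("timestamps must be strictly increasing")
        bad = np.flatnonzero(np.abs(dt - step) > step * 1e-3)
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-uniform sampling: gap of {dt[i]:.6g} s between rows "
                f"{i} and {i + 1} (t = {t[i]:.6g} s), expected {step:.6g} s"
            )
        fs = fs_override if fs_override is not None else 1.0 / step
        return PressureWaveform(x, fs=fs, start_time=float(t[0]),
                                subject_id=subject_id, phase_label=phase_label)

    x = data[:, 0]
    if fs_override is not None:
        fs = float(fs_override)
    elif "fs_hz" in meta:
        fs = float(meta["fs_hz"])
    else:
        raise ValueError(f"one-column file {path} has no '# fs_hz' header and no fs_override")
    start = float(meta.get("start_time_s", 0.0))
    return PressureWaveform(x, fs=fs, start_time=start,
                            subject_id=subject_id, phase_label=phase_label)


def _sniff_delimiter(path: Path, skiprows: int) -> Optional[str]:
    """Return ',' or '\\t' if the first data line uses them, else None (whitespace)."""
    with open(path) as fh:
        for _ in range(skiprows):
            fh.readline()
        line = fh.readline()
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None


def write_waveform(wave: PressureWaveform, path, include_time: bool = True,
                   extra_header: Optional[dict] = None) -> None:
    """Write a waveform as delimited text with a ``#`` header.

    ``include_time=True`` writes ``time_s,pressure_mmHg`` rows at full float
    precision so a write/read round trip is exact; otherwise a single pressure
    column is written with fs in the header.
    """
    path = Path(path)
    header = {
        "fs_hz": repr(float(wave.fs)),
        "subject_id": wave.subject_id,
        "start_time_s": repr(float(wave.start_time)),
    }
    if wave.phase_label:
        header["phase_label"] = wave.phase_label
    if extra_header:
        header.update(extra_header)
    buf = _io.StringIO()
    for k, v in header.items():
        buf.write(f"# {k} = {v}\n")
    if include_time:
        t = wave.times
        for ti, xi in zip(t, wave.samples):
            buf.write(f"{float(ti)!r},{float(xi)!r}\n")
    else:
        for xi in wave.samples:
            buf.write(f"{float(xi)!r}\n")
    path.write_text(buf.getvalue())


def segment_windows(wave: PressureWaveform, schedule: "PhaseSchedule"
                    ) -> tuple[dict, WindowSet]:
    """Cut a recording into phase segments and 5-minute analysis windows.

    Boundaries are half-open sample ranges ``[start, end)`` computed from the
    cumulative schedule times, so concatenating a phase's windows reproduces
    the phase segment sample-for-sample.  A recording longer than the
    schedule is trimmed at the end; a shorter one is an error reporting the
    shortfall.

    Returns
    -------
    (phases, windows) : dict[str, PressureWaveform], WindowSet
    """
    fs = wave.fs
    total = schedule.total_duration
    if wave.duration + 0.5 / fs < total:
        raise ValueError(
            f"recording of {wave.duration:.3f} s is {total - wave.duration:.3f} s "
            f"shorter than the {total:.0f} s schedule"
        )

    phases: dict = {}
    windows: dict = {}
    win_phase: dict = {}
    t0 = 0.0
    for phase in schedule.phases:
        a = int(round(t0 * fs))
        b = int(round((t0 + phase.duration) * fs))
        phases[phase.name] = PressureWaveform(
            wave.samples[a:b], fs=fs, start_time=wave.start_time + a / fs,
            subject_id=wave.subject_id, phase_label=phase.name,
        )
        n_sub = int(round(phase.duration / schedule.subwindow_duration))
        for j in range(n_sub):
            w0 = t0 + j * schedule.subwindow_duration
            w1 = w0 + schedule.subwindow_duration
            ia = int(round(w0 * fs))
            ib = int(round(w1 * fs))
            label = _window_label(w1)
            windows[label] = PressureWaveform(
                wave.samples[ia:ib], fs=fs, start_time=wave.start_time + ia / fs,
                subject_id=wave.subject_id, phase_label=phase.name,
            )
            win_phase[label] = phase.name
        t0 += phase.duration
    return phases, WindowSet(windows=windows, phases=win_phase)


def _window_label(end_seconds: float):
    """Group label = minute at which the window ends (int when integral)."""
    minutes = end_seconds / 60.0
    return int(round(minutes)) if abs(minutes - round(minutes)) < 1e-9 else round(minutes, 3)
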