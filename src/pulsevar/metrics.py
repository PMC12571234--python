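"""The seven pulse-rate-variability metrics and the per-window pipeline.

Time domain (computed directly on the N-N series):

* ``mean_nn`` — mean N-N interval, ms;
* ``sdnn``    — sample standard deviation of N-N intervals, ms;
* ``rmssd``   — root mean squared successive difference, ms, computed only
  over pairs of intervals that were adjacent *before* artifact rejection, so
  a gap left by a dropped beat never contributes an inflated difference.

Frequency domain (computed on the uniformly resampled tachogram):

* ``lf_power``  — band power over 0.04-0.15 Hz, ms^2 (mixed sympathetic and
  parasympathetic modulation);
* ``hf_power``  — band power over 0.15-0.4 Hz, ms^2 (mainly parasympathetic);
* ``total_power`` — band power over 0-0.4 Hz, ms^2;
* ``lf_hf_ratio`` — LF/HF, the usual sympathovagal balance index.

The tachogram is the N-N series cubic-spline interpolated onto a uniform
4 Hz grid and demeaned; its spectrum is a Welch averaged periodogram (Hann
window, 50% overlap, segments of up to 256 s) normalised as a density, so
the integral over frequency recovers the tachogram variance.  Band edges
are half-open with 0.15 Hz belonging to HF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .beats import DetectorSettings, detect_beats, pp_intervals
from .intervals import AdaptiveFilterSettings, IntervalSeries, adaptive_filter
from .io import PressureWaveform, WindowSet
from .preprocess import FilterSettings, lowpass

__all__ = [
    "PRVMetrics", "FrequencyBands", "Tachogram", "SpectralDensity",
    "time_domain", "resample_tachogram", "power_spectrum", "band_power",
    "frequency_domain", "prv_metrics", "compute_window_metrics",
    "compute_phase_metrics", "PipelineSettings", "METRIC_NAMES",
]

METRIC_NAMES = ("mean_nn", "sdnn", "rmssd", "lf_power", "hf_power",
                "total_power", "lf_hf_ratio")


@dataclass(frozen=True)
class PRVMetrics:
    """The seven PRV metrics for one analysis window."""

    mean_nn: float
    sdnn: float
    rmssd: float
    lf_power: float
    hf_power: float
    total_power: float
    lf_hf_ratio: float  # NaN when hf_power == 0

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FrequencyBands:
    """Half-open spectral bands in Hz; the 0.15 Hz edge belongs to HF."""

    lf: tuple = (0.04, 0.15)
    hf: tuple = (0.15, 0.40)
    total: tuple = (0.0, 0.40)

    def __post_init__(self) -> None:
        for name in ("lf", "hf", "total"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"band {name} must satisfy 0 <= lower < upper")
        if self.lf[1] != self.hf[0]:
            raise ValueError("lf upper edge must equal hf lower edge")


@dataclass(frozen=True)
class Tachogram:
    """Uniformly resampled, demeaned N-N series."""

    values: np.ndarray
    fs_resample: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.fs_resample > 0.8:  # must resolve the 0.4 Hz band edge
            raise ValueError("fs_resample must exceed twice the 0.4 Hz band edge")


@dataclass(frozen=True)
class SpectralDensity:
    """One-sided power spectral density of a tachogram, ms^2/Hz."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.density.shape:
            raise ValueError("frequencies and density must have equal shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")


def time_domain(nn: IntervalSeries) -> tuple[float, float, float]:
    """Mean, SDNN and RMSSD of an N-N series.

    RMSSD uses only originally adjacent kept pairs (``parent_index``
    difference of exactly 1).

    Raises
    ------
    ValueError
        Naming the metric that cannot be computed: fewer than 2 intervals
        (mean/SDNN) or fewer than 2 adjacent pairs (RMSSD).
    """
    if nn.kind != "NN":
        raise ValueError(f"time_domain expects an NN series, got kind={nn.kind!r}")
    v = nn.values
    if v.size < 2:
        raise ValueError("mean/SDNN need at least 2 N-N intervals")
    mean_nn = float(v.mean())
    sdnn = float(v.std(ddof=1))
    adjacent = np.diff(nn.parent_index) == 1
    diffs = np.diff(v)[adjacent]
    if diffs.size < 2:
        raise ValueError("RMSSD needs at least 2 originally adjacent kept pairs")
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))
    return mean_nn, sdnn, rmssd


def resample_tachogram(nn: IntervalSeries, fs_resample: float = 4.0) -> Tachogram:
    """Cubic interpolation of (timestamp, value) pairs onto a uniform grid.

    The grid spans the kept intervals' timestamps; the mean is removed
    after resampling.

    Raises
    ------
    ValueError
        With fewer than 4 kept intervals or a span under 60 s.
    """
    if len(nn) < 4:
        raise ValueError(f"need at least 4 intervals to resample, got {len(nn)}")
    if nn.span < 60.0:
        raise ValueError(f"series spans {nn.span:.1f} s; at least 60 s required")
    spline = CubicSpline(nn.timestamps, nn.values)
    n = int(np.floor(nn.span * fs_resample)) + 1
    grid = nn.timestamps[0] + np.arange(n) / fs_resample
    x = spline(grid)
    x = x - x.mean()
    return Tachogram(values=x, fs_resample=fs_resample, start_time=float(grid[0]))


def power_spectrum(tg: Tachogram, max_segment_seconds: float = 256.0) -> SpectralDensity:
    """Welch averaged-periodogram density of a tachogram.

    Hann window, 50% overlap, segment length capped at
    ``max_segment_seconds`` of samples; density normalisation, so the
    trapezoidal integral over frequency approximates the tachogram variance.

    Raises
    ------
    ValueError
        For tachograms shorter than 128 samples.
    """
    x = tg.values
    if x.size < 128:
        raise ValueError(f"tachogram of {x.size} samples is too short (need >= 128)")
    nperseg = int(min(x.size, round(max_segment_seconds * tg.fs_resample)))
    f, pxx = welch(x, fs=tg.fs_resample, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2, detrend="constant", scaling="density")
    return SpectralDensity(frequencies=f, density=np.maximum(pxx, 0.0))


def band_power(sd: SpectralDensity, band: tuple) -> float:
    """Trapezoidal integral of the density over the half-open band [lo, hi).

    Raises
    ------
    ValueError
        If the band lies outside the spectral grid.
    """
    lo, hi = band
    f = sd.frequencies
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError(
            f"band [{lo}, {hi}) outside spectral range [{f[0]:.4g}, {f[-1]:.4g}]"
        )
    sel = (f >= lo) & (f < hi)
    if np.count_nonzero(sel) < 2:
        raise ValueError(f"band [{lo}, {hi}) contains fewer than 2 frequency points")
    return float(np.trapezoid(sd.density[sel], f[sel]))


def frequency_domain(nn: IntervalSeries,
                     bands: FrequencyBands = FrequencyBands(),
                     fs_resample: float = 4.0) -> tuple[float, float, float, float]:
    """LF, HF, total power (ms^2) and the LF/HF ratio of an N-N series.

    A zero HF power makes the ratio undefined; NaN is returned with a
    warning rather than a silent infinity.
    """
    tg = resample_tachogram(nn, fs_resample=fs_resample)
    sd = power_spectrum(tg)
    lf = band_power(sd, bands.lf)
    hf = band_power(sd, bands.hf)
    total = band_power(sd, bands.total)
    if hf > 0:
        ratio = lf / hf
    else:
        warnings.warn("HF power is zero; LF/HF ratio undefined (NaN)")
        ratio = float("nan")
    return lf, hf, total, ratio


def prv_metrics(nn: IntervalSeries,
                bands: FrequencyBands = FrequencyBands(),
                fs_resample: float = 4.0) -> PRVMetrics:
    """All seven PRV metrics for one window."""
    mean_nn, sdnn, rmssd = time_domain(nn)
    lf, hf, total, ratio = frequency_domain(nn, bands=bands, fs_resample=fs_resample)
    return PRVMetrics(mean_nn=mean_nn, sdnn=sdnn, rmssd=rmssd, lf_power=lf,
                      hf_power=hf, total_power=total, lf_hf_ratio=ratio)


@dataclass(frozen=True)
class PipelineSettings:
    """Per-window processing settings for the full filter->detect->NN->metrics chain."""

    filter: FilterSettings = field(default_factory=FilterSettings)
    detector: DetectorSettings = field(default_factory=DetectorSettings)
    nn: AdaptiveFilterSettings = field(default_factory=AdaptiveFilterSettings)
    bands: FrequencyBands = field(default_factory=FrequencyBands)
    fs_resample: float = 4.0


def analyze_segment(wave: PressureWaveform,
                    settings: PipelineSettings = PipelineSettings()) -> PRVMetrics:
    """Run the full chain (low-pass, detect, P-P, N-N, metrics) on one segment."""
    filtered = lowpass(wave, settings.filter)
    beats = detect_beats(filtered, settings.detector)
    pp = pp_intervals(beats)
    nn = adaptive_filter(pp, settings.nn)
    return prv_metrics(nn, bands=settings.bands, fs_resample=settings.fs_resample)


def compute_window_metrics(windows: WindowSet,
                           settings: PipelineSettings = PipelineSettings(),
                           subject_id: Optional[str] = None
                           ) -> tuple[pd.DataFrame, dict]:
    """Metrics for every 5-minute window, independently per window.

    Returns a tidy table with columns ``subject_id, group_label, phase,
    metric, value`` and a dict mapping failed window labels to the error
    message; one bad window never aborts the rest.
    """
    rows = []
    failures: dict = {}
    for label, wave, phase in windows:
        sid = subject_id if subject_id is not None else wave.subject_id
        try:
            m = analyze_segment(wave, settings)
        except (ValueError, RuntimeError) as exc:
            failures[label] = f"window {label}: {exc}"
            continue
        for name, value in m.as_dict().items():
            rows.append({"subject_id": sid, "group_label": label,
                         "phase": phase, "metric": name, "value": value})
    return pd.DataFrame(rows, columns=["subject_id", "group_label", "phase",
                                       "metric", "value"]), failures


def compute_phase_metrics(phases: dict,
                          settings: PipelineSettings = PipelineSettings(),
                          subject_id: Optional[str] = None
                          ) -> tuple[pd.DataFrame, dict]:
    """Metrics for each 15-minute phase segment, same chain as the windows."""
    rows = []
    failures: dict = {}
    for name, wave in phases.items():
        sid = subject_id if subject_id is not None else wave.subject_id
        try:
            m = analyze_segment(wave, settings)
        except (ValueError, RuntimeError) as exc:
            failures[name] = f"phase {name}: {exc}"
            continue
        for metric, value in m.as_dict().items():
            rows.append({"subject_id": sid, "phase": name,
                         "metric": metric, "value": value})
    return pd.DataFrame(rows, columns=["subject_id", "phase", "metric", "value"]), failures
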