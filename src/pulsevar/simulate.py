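"""Synthetic arterial pressure waveforms with known beat timing and artifacts.

Beat times come from an integral pulse frequency modulation (IPFM) model:
the instantaneous rate

    r(t) = (mean_rate / 60) * (1 + a_lf sin(2 pi f_lf t)
                                 + a_hf sin(2 pi f_hf t) + n(t))

is integrated and a beat is emitted at every integer crossing of the
integral.  The sinusoidal terms place known modulation power at single
frequencies inside the LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands, which
makes spectral ground truth analytic; ``n(t)`` is seeded white noise
low-passed at 0.5 Hz so broadband modulation power stays in physiological
bands.  Parameters switch at phase boundaries while the integral runs on
continuously.

Each beat is rendered as an asymmetric arterial pulse — fast upstroke,
exponential decay with a small dicrotic bump — whose systolic maximum lies
exactly at the beat time (peak offset 0, the documented convention).
Artifacts (spurious pulse transients, ectopic shifts, beat dropouts, noise
bursts) are injected afterwards with a complete ground-truth event log, so
every downstream stage can be scored against known truth.

The hemorrhage preset multiplies baseline LF amplitude by 5, HF amplitude
by 2 and mean rate by 1.15 during the bleed, and returns amplitudes only
part-way toward baseline in recovery — reproducing the direction (not the
magnitude) of the autonomic response to acute blood loss: sympathetic
activation raises LF, HF, total power and LF/HF at onset; all three of LF,
total power and LF/HF fall again when the bleed stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .beats import BeatSeries
from .io import PressureWaveform

__all__ = [
    "ModulationParams", "Phase", "PhaseSchedule", "ArtifactSpec",
    "MorphologyParams", "SubjectRecord", "generate_beat_times",
    "render_pressure_waveform", "inject_artifacts", "generate_cohort",
    "hemorrhage_schedule", "add_pulse_transient",
]


@dataclass(frozen=True)
class ModulationParams:
    """Instantaneous-rate modulation for the IPFM model.

    mean_rate : float
        Mean pulse rate, beats per minute.
    a_lf, a_hf : float
        Dimensionless sinusoidal modulation amplitudes.
    f_lf, f_hf : float
        Modulation frequencies, Hz; constrained to the LF / HF analysis
        bands whenever the corresponding amplitude is non-zero.
    noise_sd : float
        Standard deviation of the smoothed broadband rate modulation.
    seed : int
        Seed for the broadband noise.
    """

    mean_rate: float = 90.0
    a_lf: float = 0.03
    f_lf: float = 0.10
    a_hf: float = 0.025
    f_hf: float = 0.30
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_rate > 0:
            raise ValueError(f"mean_rate must be positive, got {self.mean_rate}")
        if self.a_lf < 0 or self.a_hf < 0 or self.noise_sd < 0:
            raise ValueError("modulation amplitudes must be non-negative")
        if self.a_lf + self.a_hf + 3 * self.noise_sd >= 1:
            raise ValueError(
                "a_lf + a_hf + 3*noise_sd must stay below 1 so the "
                "instantaneous rate remains positive"
            )
        if self.a_lf > 0 and not (0.04 <= self.f_lf <= 0.15):
            raise ValueError(f"f_lf={self.f_lf} outside the LF band [0.04, 0.15] Hz")
        if self.a_hf > 0 and not (0.15 < self.f_hf <= 0.40):
            raise ValueError(f"f_hf={self.f_hf} outside the HF band (0.15, 0.4] Hz")


@dataclass(frozen=True)
class Phase:
    """One protocol phase: a name, a duration and its modulation parameters."""

    name: str
    duration: float = 900.0
    modulation: ModulationParams = field(default_factory=ModulationParams)

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("phase duration must be positive")


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered protocol phases plus the analysis subwindow length.

    Defaults give the standard protocol: baseline / hemorrhage / recovery,
    900 s each, cut into 300 s subwindows -> nine windows labelled
    5, 10, ..., 45 by the minute at which each ends.
    """

    phases: tuple = ()
    subwindow_duration: float = 300.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        if not self.subwindow_duration > 0:
            raise ValueError("subwindow_duration must be positive")
        for p in self.phases:
            k = p.duration / self.subwindow_duration
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"subwindow_duration {self.subwindow_duration} s must divide "
                    f"phase {p.name!r} duration {p.duration} s"
                )

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    @property
    def window_labels(self) -> list:
        from .io import _window_label
        labels, t = [], 0.0
        for p in self.phases:
            n = int(round(p.duration / self.subwindow_duration))
            for j in range(n):
                labels.append(_window_label(t + (j + 1) * self.subwindow_duration))
            t += p.duration
        return labels


def hemorrhage_schedule(baseline: ModulationParams = ModulationParams(),
                        phase_duration: float = 900.0,
                        subwindow_duration: float = 300.0) -> PhaseSchedule:
    """Standard three-phase protocol with the hemorrhage preset.

    During the bleed: LF amplitude x5, HF amplitude x2, mean rate x1.15
    (sympathetic activation and tachycardia).  Recovery returns amplitudes
    part-way toward baseline (LF x2, HF x1.5, rate x1.05) — autonomic tone
    does not normalise immediately after a 20% blood-volume loss.
    """
    during = replace(baseline,
                     mean_rate=baseline.mean_rate * 1.15,
                     a_lf=baseline.a_lf * 5.0,
                     a_hf=baseline.a_hf * 2.0,
                     seed=baseline.seed + 1)
    recovery = replace(baseline,
                       mean_rate=baseline.mean_rate * 1.05,
                       a_lf=baseline.a_lf * 2.0,
                       a_hf=baseline.a_hf * 1.5,
                       seed=baseline.seed + 2)
    return PhaseSchedule(
        phases=(Phase("baseline", phase_duration, baseline),
                Phase("hemorrhage", phase_duration, during),
                Phase("recovery", phase_duration, recovery)),
        subwindow_duration=subwindow_duration,
    )


@dataclass(frozen=True)
class ArtifactSpec:
    """Artifact injection rates (events per minute) and noise level.

    spurious_peak_rate : extra pulse-like transients between true beats.
    ectopic_shift_rate : beats moved earlier by 20-40% of the local interval.
    dropout_rate : beats flattened out of the waveform (missed-beat gaps).
    noise_burst_sd : mmHg standard deviation of added Gaussian burst noise.
    """

    spurious_peak_rate: float = 0.0
    ectopic_shift_rate: float = 0.0
    dropout_rate: float = 0.0
    noise_burst_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spurious_peak_rate", "ectopic_shift_rate",
                     "dropout_rate", "noise_burst_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MorphologyParams:
    """Arterial pulse shape parameters.

    The pulse is asymmetric: a cosine upstroke over ``upstroke_fraction`` of
    the local interval ending exactly at the systolic peak, then an
    exponential decay (time constant ``decay_tau`` s) toward diastole with a
    Gaussian dicrotic bump of relative amplitude ``dicrotic_fraction``
    centred ``dicrotic_delay`` s after the peak.
    """

    systolic_pressure: float = 120.0
    diastolic_pressure: float = 80.0
    upstroke_fraction: float = 0.18
    decay_tau: float = 0.20
    dicrotic_fraction: float = 0.10
    dicrotic_delay: float = 0.25
    measurement_noise_sd: float = 0.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not self.systolic_pressure > self.diastolic_pressure > 0:
            raise ValueError("require systolic_pressure > diastolic_pressure > 0")
        if not 0 < self.upstroke_fraction < 0.5:
            raise ValueError("upstroke_fraction must be in (0, 0.5)")
        if self.decay_tau <= 0 or self.dicrotic_delay <= 0:
            raise ValueError("decay_tau and dicrotic_delay must be positive")
        if not 0 <= self.dicrotic_fraction < 0.3:
            raise ValueError("dicrotic_fraction must be in [0, 0.3)")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be non-negative")


def _smoothed_noise(n: int, grid_fs: float, sd: float, rng: np.random.Generator
                    ) -> np.ndarray:
    """White noise low-passed at 0.5 Hz, rescaled to standard deviation sd."""
    w = rng.standard_normal(n)
    if n < 30 or sd == 0:
        return np.zeros(n)
    sos = butter(4, 0.5, btype="low", fs=grid_fs, output="sos")
    y = sosfiltfilt(sos, w)
    s = y.std()
    return y * (sd / s) if s > 0 else np.zeros(n)


def generate_beat_times(schedule: PhaseSchedule, grid_fs: float = 200.0) -> BeatSeries:
    """Ground-truth beat times from the IPFM model.

    The rate signal is built on a ``grid_fs`` grid, integrated by the
    trapezoidal rule, and beat times are the linearly interpolated crossings
    of successive integer thresholds.  Identical schedule (including seeds)
    gives bit-identical output.
    """
    total = schedule.total_duration
    n = int(round(total * grid_fs)) + 1
    t = np.arange(n) / grid_fs

    rate = np.empty(n)
    t0 = 0.0
    for phase in schedule.phases:
        m = phase.modulation
        sel = (t >= t0 - 1e-12) & (t < t0 + phase.duration - 1e-12) if t0 + phase.duration < total \
            else (t >= t0 - 1e-12)
        tt = t[sel]
        rng = np.random.default_rng(m.seed)
        noise = _smoothed_noise(tt.size, grid_fs, m.noise_sd, rng)
        mod = (1.0 + m.a_lf * np.sin(2 * np.pi * m.f_lf * tt)
               + m.a_hf * np.sin(2 * np.pi * m.f_hf * tt) + noise)
        rate[sel] = (m.mean_rate / 60.0) * np.maximum(mod, 0.05)
        t0 += phase.duration

    # trapezoidal cumulative integral of the rate
    integral = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0))) / grid_fs

    n_beats = int(np.floor(integral[-1]))
    thresholds = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integral, thresholds)  # first sample with integral >= k
    lo = idx - 1
    frac = (thresholds - integral[lo]) / (integral[idx] - integral[lo])
    times = t[lo] + frac / grid_fs
    return BeatSeries(times=times)


def render_pressure_waveform(beats: BeatSeries, morphology: MorphologyParams,
                             fs: float, duration: Optional[float] = None
                             ) -> PressureWaveform:
    """Render one asymmetric pulse per beat into a sampled pressure trace.

    The systolic maximum of each pulse falls within one sample of the beat
    time itself (peak offset zero).  The trace covers ``duration`` seconds
    (default: last beat plus one median interval), giving
    ``ceil(duration * fs)`` samples.

    Raises
    ------
    ValueError
        For an empty beat series or ``fs`` below 100 Hz (too coarse to
        resolve the upstroke).
    """
    if len(beats) == 0:
        raise ValueError("cannot render a waveform from an empty beat series")
    if fs < 100:
        raise ValueError(f"fs={fs} Hz is too low to resolve arterial pulses (need >= 100)")
    bt = beats.times
    med = float(np.median(np.diff(bt))) if len(bt) > 1 else 60.0 / 90.0
    if duration is None:
        duration = float(bt[-1] + med)
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs

    dia = morphology.diastolic_pressure
    amp = morphology.systolic_pressure - dia
    tau = morphology.decay_tau
    x = np.full(n, dia)

    # anchor points: synthetic pre/post peaks so edge segments get a shape
    anchors = np.concatenate(([bt[0] - med], bt, [bt[-1] + med]))
    for k in range(len(anchors) - 1):
        p0, p1 = anchors[k], anchors[k + 1]
        interval = p1 - p0
        t_up = morphology.upstroke_fraction * interval
        i0 = max(0, int(np.ceil(p0 * fs)))
        i1 = min(n, int(np.ceil(p1 * fs)))
        if i1 <= i0:
            continue
        ts = t[i0:i1]
        seg = np.empty(ts.size)
        rel = ts - p0
        if k == 0:
            # before the first real beat there is no preceding pulse to decay
            # from; hold diastole until the first upstroke
            decay = np.full(ts.size, dia)
        else:
            decay = dia + amp * np.exp(-rel / tau)
            if morphology.dicrotic_fraction > 0:
                decay = decay + amp * morphology.dicrotic_fraction * np.exp(
                    -0.5 * ((rel - morphology.dicrotic_delay) / 0.03) ** 2)
        in_decay = ts < p1 - t_up
        seg[in_decay] = decay[in_decay]
        # cosine upstroke from the decay value at ramp start up to systole at p1
        ramp_start = p1 - t_up
        rel0 = ramp_start - p0
        v0 = dia if k == 0 else dia + amp * np.exp(-rel0 / tau)
        up = ~in_decay
        phase = (ts[up] - ramp_start) / t_up
        seg[up] = v0 + (morphology.systolic_pressure - v0) * 0.5 * (1 - np.cos(np.pi * phase))
        x[i0:i1] = seg

    if morphology.measurement_noise_sd > 0:
        rng = np.random.default_rng(morphology.noise_seed)
        x = x + rng.normal(0.0, morphology.measurement_noise_sd, n)
    return PressureWaveform(x, fs=fs)


def add_pulse_transient(wave: PressureWaveform, time: float, amplitude: float,
                        width: float = 0.04) -> PressureWaveform:
    """Add one narrow pulse-like Gaussian transient at ``time`` (seconds).

    Used by the artifact injector for spurious detections; exposed so tests
    can place a transient deterministically.
    """
    t = wave.times
    bump = amplitude * np.exp(-0.5 * ((t - time) / width) ** 2)
    return PressureWaveform(wave.samples + bump, fs=wave.fs,
                            start_time=wave.start_time, subject_id=wave.subject_id,
                            phase_label=wave.phase_label)


def _pulse_amplitude(x: np.ndarray) -> float:
    return float(np.percentile(x, 98) - np.percentile(x, 2))


def inject_artifacts(wave: PressureWaveform, beats: BeatSeries, spec: ArtifactSpec
                     ) -> tuple[PressureWaveform, pd.DataFrame]:
    """Inject seeded artifacts into a rendered waveform.

    Returns the corrupted waveform and a ground-truth log with one row per
    injected event (columns ``time_s, kind, detail``).  All rates zero gives
    a waveform identical to the input and an empty log.
    """
    rng = np.random.default_rng(spec.seed)
    x = wave.samples.copy()
    fs = wave.fs
    duration_min = wave.duration / 60.0
    amp = _pulse_amplitude(x)
    bt = beats.times
    events: list[dict] = []

    n_spur = rng.poisson(spec.spurious_peak_rate * duration_min)
    for _ in range(n_spur):
        if len(bt) < 2:
            break
        k = int(rng.integers(0, len(bt) - 1))
        u = rng.uniform(0.3, 0.7)
        tev = bt[k] + u * (bt[k + 1] - bt[k])
        t = wave.times
        x += 0.7 * amp * np.exp(-0.5 * ((t - tev) / 0.02) ** 2)
        events.append({"time_s": tev, "kind": "spurious_peak", "detail": 0.7 * amp})

    n_ect = rng.poisson(spec.ectopic_shift_rate * duration_min)
    for _ in range(n_ect):
        if len(bt) < 4:
            break
        k = int(rng.integers(1, len(bt) - 1))
        interval = bt[k] - bt[k - 1]
        shift = rng.uniform(0.2, 0.4) * interval
        _move_peak(x, fs, bt[k], bt[k] - shift, bt[k - 1], amp)
        events.append({"time_s": bt[k], "kind": "ectopic_shift", "detail": shift})

    n_drop = rng.poisson(spec.dropout_rate * duration_min)
    for _ in range(n_drop):
        if len(bt) < 4:
            break
        k = int(rng.integers(1, len(bt) - 1))
        a = int(round((bt[k] - 0.5 * (bt[k] - bt[k - 1])) * fs))
        b = int(round((bt[k] + 0.5 * (bt[k + 1] - bt[k])) * fs))
        a, b = max(0, a), min(len(x), b)
        if b - a > 2:
            x[a:b] = np.linspace(x[a], x[b - 1], b - a)
        events.append({"time_s": bt[k], "kind": "dropout", "detail": float(b - a) / fs})

    if spec.noise_burst_sd > 0:
        n_burst = rng.poisson(1.0 * duration_min)  # ~1 burst/min when enabled
        for _ in range(n_burst):
            start = rng.uniform(0, max(wave.duration - 2.0, 0.1))
            dur = rng.uniform(0.5, 2.0)
            a = int(round(start * fs))
            b = min(len(x), int(round((start + dur) * fs)))
            x[a:b] += rng.normal(0.0, spec.noise_burst_sd, b - a)
            events.append({"time_s": start, "kind": "noise_burst", "detail": dur})

    log = pd.DataFrame(events, columns=["time_s", "kind", "detail"])
    out = PressureWaveform(x, fs=fs, start_time=wave.start_time,
                           subject_id=wave.subject_id, phase_label=wave.phase_label)
    return out, log


def _move_peak(x: np.ndarray, fs: float, t_old: float, t_new: float,
               t_prev: float, amp: float) -> None:
    """Rewrite the segment around one beat so its peak sits at ``t_new``.

    The window from 30% into the preceding interval to just past the old
    peak is replaced by an upstroke to the local maximum at ``t_new``
    followed by an exponential decay, blended back into the original
    signal at the window edges.
    """
    w0 = t_prev + 0.3 * (t_old - t_prev)
    w1 = t_old + 0.1 * (t_old - t_prev)
    a = max(0, int(round(w0 * fs)))
    b = min(len(x), int(round(w1 * fs)))
    if b - a < 6:
        return
    t = np.arange(a, b) / fs
    v0, v1 = x[a], x[b - 1]
    peak = max(x[a:b].max(), v0 + 0.5 * amp)
    seg = np.empty(b - a)
    up = t <= t_new
    t_up = max(t_new - w0, 2.0 / fs)
    seg[up] = v0 + (peak - v0) * 0.5 * (1 - np.cos(np.pi * np.clip((t[up] - w0) / t_up, 0, 1)))
    down = ~up
    tau = 0.15
    seg[down] = v1 + (peak - v1) * np.exp(-(t[down] - t_new) / tau)
    # linear blend over 15 ms at each edge to avoid steps
    nb = min(int(0.015 * fs), (b - a) // 4)
    if nb > 0:
        ramp = np.linspace(0, 1, nb)
        seg[:nb] = (1 - ramp) * x[a:a + nb] + ramp * seg[:nb]
        seg[-nb:] = (1 - ramp[::-1]) * x[b - nb:b] + ramp[::-1] * seg[-nb:]
    x[a:b] = seg


@dataclass
class SubjectRecord:
    """One simulated subject: waveform, ground-truth beats, artifact log."""

    subject_id: str
    waveform: PressureWaveform
    true_beats: BeatSeries
    artifact_log: pd.DataFrame
    schedule: PhaseSchedule
    morphology: MorphologyParams
    artifacts: ArtifactSpec


def generate_cohort(n_subjects: int = 4,
                    schedule: Optional[PhaseSchedule] = None,
                    morphology: MorphologyParams = MorphologyParams(),
                    artifacts: ArtifactSpec = ArtifactSpec(),
                    master_seed: int = 0,
                    fs: float = 1000.0,
                    jitter: bool = True) -> list:
    """Simulate a cohort of subjects with deterministic per-subject seeds.

    Subject-level jitter draws, per subject, a mean-rate factor in
    [0.95, 1.05], a modulation-amplitude factor in [0.9, 1.1] and a pressure
    factor in [0.95, 1.05], applied across all phases (a subject trait).
    With ``jitter=False`` and ``n_subjects=1`` the output equals a single
    generate/render/inject chain with the derived seeds.

    Raises
    ------
    ValueError
        If ``n_subjects < 1``.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if schedule is None:
        schedule = hemorrhage_schedule()
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(4 * n_subjects) % (2 ** 31)

    cohort = []
    for i in range(n_subjects):
        s_mod, s_art, s_noise, s_jit = (int(seeds[4 * i + j]) for j in range(4))
        if jitter:
            jrng = np.random.default_rng(s_jit)
            f_rate = jrng.uniform(0.95, 1.05)
            f_amp = jrng.uniform(0.90, 1.10)
            f_press = jrng.uniform(0.95, 1.05)
        else:
            f_rate = f_amp = f_press = 1.0

        phases = tuple(
            replace(p, modulation=replace(
                p.modulation,
                mean_rate=p.modulation.mean_rate * f_rate,
                a_lf=p.modulation.a_lf * f_amp,
                a_hf=p.modulation.a_hf * f_amp,
                seed=(p.modulation.seed + s_mod) % (2 ** 31),
            ))
            for p in schedule.phases
        )
        subj_schedule = PhaseSchedule(phases=phases,
                                      subwindow_duration=schedule.subwindow_duration)
        morph = replace(morphology,
                        systolic_pressure=morphology.systolic_pressure * f_press,
                        diastolic_pressure=morphology.diastolic_pressure * f_press,
                        noise_seed=s_noise)
        beats = generate_beat_times(subj_schedule)
        wave = render_pressure_waveform(beats, morph, fs=fs,
                                        duration=subj_schedule.total_duration)
        art = replace(artifacts, seed=s_art)
        wave, log = inject_artifacts(wave, beats, art)
        sid = f"subject_{i + 1}"
        wave.subject_id = sid
        cohort.append(SubjectRecord(subject_id=sid, waveform=wave,
                                    true_beats=beats, artifact_log=log,
                                    schedule=subj_schedule, morphology=morph,
                                    artifacts=art))
    return cohort
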