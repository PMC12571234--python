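"""Shared fixtures: small simulated signals with known ground truth."""

import numpy as np
import pytest

from pulsevar.simulate import (ModulationParams, MorphologyParams, Phase,
                               PhaseSchedule, generate_beat_times,
                               render_pressure_waveform)


def single_phase_schedule(duration=900.0, **mod_kwargs) -> PhaseSchedule:
    """One-phase schedule with the given modulation parameters."""
    return PhaseSchedule(
        phases=(Phase("baseline", duration, ModulationParams(**mod_kwargs)),),
        subwindow_duration=duration,
    )


@pytest.fixture(scope="session")
def steady_beats():
    """Unmodulated 100 bpm beats over 60 s: intervals exactly 600 ms."""
    sched = single_phase_schedule(60.0, mean_rate=100, a_lf=0, a_hf=0, noise_sd=0)
    return generate_beat_times(sched)


@pytest.fixture(scope="session")
def modulated_nn():
    """N-N series from a 900 s LF+HF modulated simulation (artifact-free)."""
    from pulsevar.beats import pp_intervals
    from pulsevar.intervals import adaptive_filter

    sched = single_phase_schedule(900.0, mean_rate=90, a_lf=0.05, f_lf=0.10,
                                  a_hf=0.03, f_hf=0.30, noise_sd=0.005, seed=11)
    beats = generate_beat_times(sched)
    return adaptive_filter(pp_intervals(beats))


@pytest.fixture(scope="session")
def clean_waveform():
    """Rendered noiseless waveform for ~150 unmodulated beats at 250 Hz."""
    sched = single_phase_schedule(90.0, mean_rate=100, a_lf=0, a_hf=0, noise_sd=0)
    beats = generate_beat_times(sched)
    wave = render_pressure_waveform(beats, MorphologyParams(), fs=250.0,
                                    duration=90.0)
    return wave, beats


def match_beats(detected: np.ndarray, truth: np.ndarray, tol: float = 0.030):
    """Greedy one-to-one matching of detected to true beat times.

    Returns (n_matched, n_detected, n_truth); independent of the detector.
    """
    used = np.zeros(truth.size, dtype=bool)
    n_match = 0
    for t in detected:
        d = np.abs(truth - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            n_match += 1
    return n_match, detected.size, truth.size
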