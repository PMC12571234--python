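"""Low-pass filtering of raw pressure waveforms before beat detection.

Arterial pressure carries essentially all of its pulse information below
~20 Hz; instrument and environmental noise above that band is removed with
a 15 Hz 4th-order Butterworth filter applied forward-backward.  Zero-phase
filtering matters here because the downstream quantity of interest is peak
*timing*: any group delay would bias every pulse-to-pulse interval.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.signal import butter, sosfilt, sosfiltfilt

from .io import PressureWaveform

__all__ = ["FilterSettings", "lowpass"]


@dataclass(frozen=True)
class FilterSettings:
    """Low-pass filter configuration.

    cutoff : float
        -3 dB corner frequency in Hz (default 15).
    order : int
        Butterworth order (default 4; doubled effectively by the
        forward-backward pass).
    zero_phase : bool
        Apply the filter forward and backward (no group delay).
    """

    cutoff: float = 15.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def lowpass(wave: PressureWaveform, settings: FilterSettings = FilterSettings()
            ) -> PressureWaveform:
    """Low-pass filter a waveform, preserving its length, fs and metadata.

    Raises
    ------
    ValueError
        If the cutoff is at or above the Nyquist frequency of the waveform.
    """
    nyq = wave.fs / 2.0
    if settings.cutoff >= nyq:
        raise ValueError(
            f"cutoff {settings.cutoff} Hz must be below Nyquist {nyq} Hz for fs={wave.fs}"
        )
    sos = butter(settings.order, settings.cutoff, btype="low", fs=wave.fs, output="sos")
    if settings.zero_phase:
        y = sosfiltfilt(sos, wave.samples)
    else:
        y = sosfilt(sos, wave.samples)
    return PressureWaveform(y, fs=wave.fs, start_time=wave.start_time,
                            subject_id=wave.subject_id, phase_label=wave.phase_label)
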