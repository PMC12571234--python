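"""Show the adaptive N-N filter catching injected artifacts.

Simulates a recording, corrupts it with spurious pulse transients, ectopic
shifts, dropouts and noise bursts, and compares P-P statistics before and
after adaptive filtering, with the ground-truth artifact log alongside.
"""

from pulsevar import adaptive_filter, detect_beats, lowpass, pp_intervals
from pulsevar.simulate import (ArtifactSpec, ModulationParams, MorphologyParams,
                               Phase, PhaseSchedule, generate_beat_times,
                               inject_artifacts, render_pressure_waveform)

mod = ModulationParams(mean_rate=90, a_lf=0.05, a_hf=0.03, noise_sd=0.01, seed=2)
schedule = PhaseSchedule(phases=(Phase("baseline", 900.0, mod),),
                         subwindow_duration=900.0)
beats = generate_beat_times(schedule)
wave = render_pressure_waveform(beats, MorphologyParams(), fs=1000.0,
                                duration=900.0)
spec = ArtifactSpec(spurious_peak_rate=1.0, ectopic_shift_rate=0.5,
                    dropout_rate=0.3, noise_burst_sd=2.0, seed=5)
corrupted, log = inject_artifacts(wave, beats, spec)
print("injected artifacts:")
print(log["kind"].value_counts().to_string())

pp = pp_intervals(detect_beats(lowpass(corrupted)))
nn = adaptive_filter(pp)
rejected = len(pp) - len(nn)
print(f"\nP-P intervals: {len(pp)}, rejected by the adaptive filter: "
      f"{rejected} ({100 * rejected / len(pp):.1f}%)")
print(f"interval SD before filtering: {pp.values.std(ddof=1):6.1f} ms")
print(f"interval SD after  filtering: {nn.values.std(ddof=1):6.1f} ms")
print("\nThe drop in SD is artifact removal, not physiology: the simulated "
      "autonomic modulation is identical in both series.")
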