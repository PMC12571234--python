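"""Full hemorrhage-protocol analysis on a simulated 4-subject cohort.

Simulates four 45-minute recordings (baseline / hemorrhage / recovery,
15 min each) with the hemorrhage preset (sympathetic activation: LF x5,
HF x2, rate +15% during the bleed), runs the complete per-window pipeline
and prints the phase-comparison statistics.  Runtime ~15 s.
"""

import warnings

import pandas as pd

from pulsevar import (compute_phase_metrics, compute_window_metrics,
                      phase_report, segment_windows)
from pulsevar.simulate import ArtifactSpec, generate_cohort

artifacts = ArtifactSpec(spurious_peak_rate=0.3, ectopic_shift_rate=0.2,
                         dropout_rate=0.1, noise_burst_sd=2.0)
cohort = generate_cohort(4, artifacts=artifacts, master_seed=1)

phase_parts, window_parts = [], []
for rec in cohort:
    phases, windows = segment_windows(rec.waveform, rec.schedule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pdf, _ = compute_phase_metrics(phases, subject_id=rec.subject_id)
        wdf, _ = compute_window_metrics(windows, subject_id=rec.subject_id)
    phase_parts.append(pdf)
    window_parts.append(wdf)

report = phase_report(pd.concat(phase_parts), pd.concat(window_parts))

pc = report.percent_changes
print("median percent change across subjects (15-minute phases):")
med = pc.groupby(["comparison", "metric"])["percent"].median().unstack(0).round(1)
print(med[["baseline_to_hemorrhage", "hemorrhage_to_recovery"]].to_string())

print("\nTukey HSD: hemorrhage windows significantly different from "
      "baseline/recovery windows (family-wise alpha 0.05):")
counts = report.summary.groupby(["metric", "other_phase"]).size().unstack(fill_value=0)
print(counts.to_string())
print("\n9 means every during-hemorrhage 5-min window differs from every "
      "window of that phase (3 x 3 pairs).")
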