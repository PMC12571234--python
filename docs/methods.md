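# Methods

## Scope and data model

`pulsevar` analyses continuous single-channel arterial pressure recordings
(mmHg, nominally 1000 Hz) collected under a three-phase exsanguination
protocol: 15 minutes of baseline, 15 minutes of hemorrhage (on the order of
20% blood volume at ~0.4 cc/s), 15 minutes of recovery. Each phase is
analysed whole and as three 5-minute windows; windows are labelled by the
minute at which they end (5, 10, …, 45), so labels 5–15 are baseline,
20–30 hemorrhage, 35–45 recovery. Windows are half-open sample ranges
`[start, end)` with 0-based indexing — a boundary sample belongs to the
later window, so no sample is duplicated and concatenating a phase's
windows reproduces the phase exactly. Recordings longer than the schedule
are trimmed at the end (protocol alignment is defined by recording start);
recordings missing trailing phases are analysed over the phases that fit,
with a warning.

## Preprocessing

A 4th-order low-pass Butterworth at 15 Hz, applied forward-backward
(`sosfiltfilt`). Arterial pulse energy lives below ~20 Hz; everything above
is instrument noise. Zero-phase filtering is essential rather than
cosmetic: the downstream quantity is peak *timing*, and a causal filter's
group delay would bias every interval. The 15 Hz value is the conventional
choice for pressure-derived PRV; it is configurable (`FilterSettings`).

## Beat detection

Systolic maxima are local maxima whose prominence exceeds
`prominence_fraction` (default 0.3) of the rolling pulse amplitude
(rolling max − rolling min over 2 s), with a 200 ms refractory resolved in
favour of the higher peak (earlier sample on exact ties). The refractory
caps detectable rate at 300 bpm, above porcine physiological maxima. The
peak fiducial is the systolic maximum, not the upstroke foot — P-P means
peak-to-peak here. These detector parameters are package choices; no
universal standard exists for pressure-pulse detection, so they are
explicit, documented and configurable.

## Adaptive N-N filter

Two rejection rules convert P-P to N-N intervals:

1. intervals < 20 ms are rejected (`rejected_short`) — incompatible with
   cardiac physiology, so necessarily detector artifacts;
2. intervals deviating from the moving-window mean by more than 3
   moving-window standard deviations are rejected (`rejected_outlier`).

Four choices the rule statement leaves open are fixed as follows:

* **window length** — 31 intervals, centered, truncated at the series
  edges (~15–20 s of context at porcine rates);
* **candidate exclusion** — the candidate is excluded from its own window
  statistics, so an extreme value cannot mask its own rejection;
* **single pass** — both rules are decided against the rule-1 survivor
  series simultaneously; rejections are not applied sequentially;
* **degenerate windows** — the window SD is floored at 1 ms, otherwise a
  constant window would reject any value differing at all from its mean.

Rejected intervals are dropped, never interpolated. The mask over the
parent P-P series records every decision for audit.

**Known limitation (pair masking).** A single artifact usually produces
*two* aberrant intervals (e.g. a spurious peak splits one interval in two).
Each lies in the other's moving window, inflating the other's SD; when the
split is asymmetric, the less deviant member can survive the 3-SD rule.
Self-exclusion prevents self-masking but not pair-masking. This is
inherent to the mean/SD form of the rule; consequences are quantified in
the tests (surviving artifact residue inflates RMSSD most, since every
surviving aberrant interval contributes two large successive differences).

With the default 200 ms detector refractory, rule 1 is vacuous — no
interval below 200 ms can reach it. It matters when the detector runs with
a permissive refractory/prominence configuration, where double-fires on a
single pulse produce millisecond-scale intervals; the cross-module test
exercises exactly that configuration, since two maxima 15 ms apart cannot
survive a 15 Hz low-pass under default detection at all.

## PRV metrics

Time domain on the N-N values: Mean; STD as the sample standard deviation
(n−1 denominator); RMS as the root mean squared successive difference
computed **only over originally adjacent kept pairs** — pairs spanning a
rejection gap are excluded, otherwise every dropped beat would inject one
artifact-inflated difference.

Frequency domain: the N-N series is cubic-spline interpolated onto a
uniform 4 Hz grid over the span of kept intervals (4 Hz comfortably
resolves the 0.4 Hz band edge) and demeaned; the spectrum is a Welch
averaged modified periodogram (Hann window, 50% overlap, segments up to
256 s) normalised as a one-sided density so its integral over frequency
recovers the tachogram variance (verified to within 5% in tests — Parseval
consistency). Band powers are trapezoidal integrals over half-open bands:
LF `[0.04, 0.15)`, HF `[0.15, 0.4)`, total `[0, 0.4)` — the 0.15 Hz edge
belongs to HF. Total power is integrated to 0.4 Hz; this upper limit is
configurable. An HF power of zero makes LF/HF undefined; it is reported as
NaN with a warning, never as a silent infinity, and NaN entries are
excluded from that metric's group statistics with a logged count. A
Lomb–Scargle path on the unevenly sampled series would avoid interpolation
bias and is a possible extension; it is not implemented.

Minimum-data contracts: spectral analysis needs ≥ 4 kept intervals spanning
≥ 60 s and a tachogram of ≥ 128 samples; RMS needs ≥ 2 adjacent kept pairs.
Violations raise errors naming the metric; in per-window batch runs the
failure is recorded against the window label and the remaining windows
proceed.

## Statistics

Per-subject percent change between consecutive phases is
100·(after−before)/before, signed, computed on the 15-minute phase
metrics. For each metric the nine 5-minute groups (n = subjects per group)
enter a classical one-way ANOVA at α = 0.05; the fully degenerate case
(all values identical) is defined as F = 0, p = 1. Normality is assessed
with the Anderson–Darling test (case with estimated mean and variance,
interpolated p-value) on group-mean-centred residuals, with q-q
coordinates returned for inspection; the result is reported only — no
nonparametric fallback is applied. Post-hoc comparison of all 36 group
pairs uses Tukey's HSD (studentized range on the pooled within-group
variance), holding family-wise error at 0.05 — not 36 separate two-group
tests. Note that the HSD-adjusted p-value dominates the *pooled-variance*
pairwise p (Fisher's LSD) by construction; it can legitimately fall below
a two-group-only t-test p, which uses different degrees of freedom. Groups
missing entirely for a subject (truncated recording) are dropped from the
comparison with a warning; subjects with undefined values for a metric are
dropped listwise for that metric.

## The simulator

Beat times follow an integral pulse frequency modulation (IPFM) model: the
instantaneous rate

    r(t) = (mean_rate/60) · (1 + a_LF sin(2π f_LF t) + a_HF sin(2π f_HF t) + n(t))

is integrated (trapezoidal rule on a 200 Hz grid) and beats fall at integer
crossings, linearly interpolated. `n(t)` is seeded white noise low-passed
at 0.5 Hz and scaled to `noise_sd`, keeping broadband modulation inside
physiological bands. IPFM with sinusoidal modulation is the standard HRV
test model because it makes spectral ground truth analytic: tachogram
modulation amplitude ≈ a·T₀ at the modulation frequency, so band fractions
and the LF/HF ratio have closed-form expectations. The invariant
`a_LF + a_HF + 3·noise_sd < 1` keeps the rate positive.

Each beat renders as an asymmetric pulse: cosine upstroke over 18% of the
local interval ending **exactly at the beat time** (peak offset zero — the
documented fiducial convention), then exponential decay (τ = 0.2 s) toward
diastole with a small Gaussian dicrotic bump (10% of pulse height, 0.25 s
after the peak, well below the 50%-height level so it never counts as a
beat). Defaults 120/80 mmHg systolic/diastolic.

Artifacts are injected additively into the rendered waveform with a
complete per-event ground-truth log: spurious pulse-like transients
(0.7× pulse amplitude, 20 ms Gaussian) between beats; ectopic shifts that
move one peak 20–40% of the local interval earlier by local segment
rewrite; dropouts that flatten one beat out of the trace; Gaussian noise
bursts of 0.5–2 s. All rates are events/minute, all draws seeded; zero
rates reproduce the input exactly.

**Default conditions.** Baseline modulation: 90 bpm, a_LF = 0.03 at
0.10 Hz, a_HF = 0.025 at 0.30 Hz, noise_sd = 0.01 — short-term variability
on the order of 2–3% of the mean interval, appropriate for an anesthetized
animal. The hemorrhage preset multiplies a_LF by 5, a_HF by 2 and the rate
by 1.15 during the bleed (sympathetic activation with tachycardia), and
returns only part-way in recovery (a_LF ×2, a_HF ×1.5, rate ×1.05):
autonomic tone does not normalise immediately after a 20% volume loss.
These presets target the *direction* of the autonomic response — LF, HF,
total power and LF/HF up at onset; LF, total power and LF/HF down at the
end — not any particular percent-change magnitude, for which no
quantitative ground truth exists. Artifact defaults are 0.3 spurious, 0.2
ectopic and 0.1 dropout events/min with 2 mmHg bursts: an anesthetized,
surgically instrumented femoral line is a clean signal, with occasional
flush, motion or measurement events — tens of events per 45-minute
recording, not hundreds. Cohorts draw per-subject traits once from the
master seed: rate ×U(0.95, 1.05), modulation amplitudes ×U(0.9, 1.1),
pressures ×U(0.95, 1.05).

**What the simulator does not emulate:** pressure-wave propagation and
reflection, respiration–blood-pressure coupling (no respiratory sinus
arrhythmia mechanism — HF power is injected directly), baroreflex dynamics,
drift in anesthesia depth, and ECG. Passing tests therefore demonstrate
that the pipeline recovers known modulation and rejects injected artifacts
under controlled conditions; they do not certify performance on real
recordings, whose artifact morphology and autonomic spectra are richer.

## Numerical choices

* IPFM integration grid 200 Hz; interval error from linear threshold
  interpolation is < 0.1 ms at physiological rates.
* Waveform rendering at 1000 Hz by default (minimum 100 Hz); sample count
  is `ceil(duration·fs)`.
* Sampling-rate inference from two-column files uses the median time step
  with uniformity enforced to 1 part in 10³; the first offending gap is
  named in the error.
* Window boundaries are computed by rounding cumulative times to samples,
  so phase and window boundaries agree exactly.
* Ties in beat detection (equal amplitude within the refractory) go to the
  earlier sample; greedy acceptance is in descending amplitude order.
* All seeds are integers below 2³¹; cohort sub-seeds derive from a
  `SeedSequence` of the master seed. Every operation is bit-reproducible
  given identical seeds.

## Problem sizes used in validation

The test suite and the acceptance script validate on: 1000 random interval
series for time-domain accuracy (10⁻⁹ relative tolerance against
plain-Python fsum arithmetic); 900 s single-subject simulations for band
recovery, LF/HF recovery (20 replicates) and filter rejection rates; a
1500 s / ~2300-beat recording for detection recall and precision (30 ms
match tolerance); 1000 null 9-group × n=4 tables for ANOVA calibration;
and the standard 4-subject, 45-minute, 1000 Hz cohort for the end-to-end
hemorrhage direction pattern. Outlier-rejection rates are measured on
outliers constructed at 5 local SDs — unambiguously beyond the 3-SD
threshold; values constructed *at* the threshold are undetectable in
principle, since the candidate's own noise moves it across the boundary.
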