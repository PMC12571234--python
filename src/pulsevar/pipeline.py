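"""Configuration-driven end-to-end runs: simulate a cohort, analyze it.

A single YAML config carries every protocol and processing parameter
(sampling rate, phase durations, filter cutoff, N-N rejection thresholds,
spectral bands, resampling rate, alpha) with the standard protocol as
defaults.  ``run_simulate`` writes per-subject waveforms, ground-truth beat
times and artifact logs; ``run_analyze`` reads waveforms, runs the full
processing chain and writes tidy metric tables plus the statistical report.
Every run emits a manifest with a SHA-256 digest per output file, so
identical configs and seeds are verifiably bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .beats import DetectorSettings
from .intervals import AdaptiveFilterSettings
from .io import PressureWaveform, read_waveform, segment_windows, write_waveform
from .metrics import (FrequencyBands, PipelineSettings, compute_phase_metrics,
                      compute_window_metrics)
from .preprocess import FilterSettings
from .simulate import (ArtifactSpec, ModulationParams, MorphologyParams,
                       generate_cohort, hemorrhage_schedule)
from .stats import PhaseReport, phase_report

__all__ = ["RunConfig", "run_simulate", "run_analyze", "load_config"]

log = logging.getLogger("pulsevar")


@dataclass
class RunConfig:
    """Everything a reproducible run needs; defaults are the standard protocol."""

    master_seed: int = 0
    n_subjects: int = 4
    fs: float = 1000.0
    phase_duration: float = 900.0
    subwindow_duration: float = 300.0
    baseline: ModulationParams = field(default_factory=ModulationParams)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    artifacts: ArtifactSpec = field(default_factory=lambda: ArtifactSpec(
        spurious_peak_rate=0.3, ectopic_shift_rate=0.2,
        dropout_rate=0.1, noise_burst_sd=2.0))
    filter: FilterSettings = field(default_factory=FilterSettings)
    detector: DetectorSettings = field(default_factory=DetectorSettings)
    nn: AdaptiveFilterSettings = field(default_factory=AdaptiveFilterSettings)
    bands: FrequencyBands = field(default_factory=FrequencyBands)
    fs_resample: float = 4.0
    alpha: float = 0.05
    jitter: bool = True
    inputs: Optional[list] = None  # waveform paths for analyze-only runs

    def __post_init__(self) -> None:
        errors = []
        if not 0 < self.alpha < 1:
            errors.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_subjects < 1:
            errors.append(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.fs < 100:
            errors.append(f"fs must be >= 100 Hz, got {self.fs}")
        if self.inputs:
            for p in self.inputs:
                if not Path(p).exists():
                    errors.append(f"input path does not exist: {p}")
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))

    def pipeline_settings(self) -> PipelineSettings:
        return PipelineSettings(filter=self.filter, detector=self.detector,
                                nn=self.nn, bands=self.bands,
                                fs_resample=self.fs_resample)

    def schedule(self):
        return hemorrhage_schedule(self.baseline, self.phase_duration,
                                   self.subwindow_duration)


_SECTION_TYPES = {
    "baseline": ModulationParams,
    "morphology": MorphologyParams,
    "artifacts": ArtifactSpec,
    "filter": FilterSettings,
    "detector": DetectorSettings,
    "nn": AdaptiveFilterSettings,
}


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are collected and rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    errors = []
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            try:
                kwargs[key] = _SECTION_TYPES[key](**value)
            except (TypeError, ValueError) as exc:
                errors.append(f"section {key}: {exc}")
        elif key == "bands":
            kwargs[key] = FrequencyBands(lf=tuple(value["lf"]), hf=tuple(value["hf"]),
                                         total=tuple(value.get("total", (0.0, 0.4))))
        elif key in RunConfig.__dataclass_fields__:
            kwargs[key] = value
        else:
            errors.append(f"unknown config key: {key}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path) -> None:
    """Round-trip the config to YAML (all generator parameters included)."""
    d = asdict(config)
    d["bands"] = {"lf": list(config.bands.lf), "hf": list(config.bands.hf),
                  "total": list(config.bands.total)}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, files: list) -> Path:
    manifest = {str(p.relative_to(outdir)): _digest(p) for p in sorted(files)}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def run_simulate(config: RunConfig, outdir) -> Path:
    """Simulate a cohort and write waveforms, beat truth, artifact logs.

    Waveforms are written one pressure column per file with fs in the
    header (compact and exactly round-trippable through read_waveform).
    Returns the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    cohort = generate_cohort(n_subjects=config.n_subjects,
                             schedule=config.schedule(),
                             morphology=config.morphology,
                             artifacts=config.artifacts,
                             master_seed=config.master_seed,
                             fs=config.fs, jitter=config.jitter)
    files = []
    boundaries = np.cumsum([p.duration for p in config.schedule().phases])
    for rec in cohort:
        wpath = outdir / f"{rec.subject_id}_waveform.csv"
        write_waveform(rec.waveform, wpath, include_time=False,
                       extra_header={"subject_id": rec.subject_id,
                                     "phase_boundaries_s": ",".join(f"{b:g}" for b in boundaries)})
        bpath = outdir / f"{rec.subject_id}_beats.csv"
        bpath.write_text("# beat_time_s\n" +
                         "".join(f"{float(t)!r}\n" for t in rec.true_beats.times))
        apath = outdir / f"{rec.subject_id}_artifacts.csv"
        rec.artifact_log.to_csv(apath, index=False)
        files += [wpath, bpath, apath]
    cpath = outdir / "config.yaml"
    dump_config(config, cpath)
    files.append(cpath)
    _write_manifest(outdir, files)
    log.info("simulate: %d subjects in %.1f s", len(cohort), time.perf_counter() - t0)
    return outdir


def _truncate_schedule(schedule, duration: float):
    """Drop trailing phases that do not fully fit into ``duration`` seconds."""
    kept, t = [], 0.0
    for p in schedule.phases:
        if t + p.duration <= duration + 1e-9:
            kept.append(p)
            t += p.duration
    if not kept:
        raise ValueError(
            f"recording of {duration:.1f} s shorter than the first "
            f"{schedule.phases[0].duration:.0f} s phase"
        )
    import dataclasses
    return dataclasses.replace(schedule, phases=tuple(kept))


def _analyze_subject(wave: PressureWaveform, config: RunConfig):
    schedule = config.schedule()
    if wave.duration + 0.5 / wave.fs < schedule.total_duration:
        schedule = _truncate_schedule(schedule, wave.duration)
        log.warning("subject %s: recording covers only %d of %d phases",
                    wave.subject_id, len(schedule.phases),
                    len(config.schedule().phases))
    phases, windows = segment_windows(wave, schedule)
    settings = config.pipeline_settings()
    pdf, pfail = compute_phase_metrics(phases, settings, subject_id=wave.subject_id)
    wdf, wfail = compute_window_metrics(windows, settings, subject_id=wave.subject_id)
    return pdf, wdf, {**pfail, **wfail}


def run_analyze(config: RunConfig, outdir,
                waveforms: Optional[list] = None) -> tuple[Path, PhaseReport]:
    """Analyze a cohort of waveforms end to end and write the report tables.

    ``waveforms`` may pass in-memory :class:`PressureWaveform` objects;
    otherwise ``config.inputs`` paths are read.  Per-subject failures are
    isolated and reported; the statistics run on whatever completed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if waveforms is None:
        if not config.inputs:
            raise ValueError("run_analyze needs waveforms or config.inputs")
        waveforms = [read_waveform(p) for p in config.inputs]

    phase_parts, window_parts, failures = [], [], {}
    for i, wave in enumerate(waveforms):
        if not wave.subject_id:
            wave.subject_id = f"subject_{i + 1}"
        t0 = time.perf_counter()
        try:
            pdf, wdf, fail = _analyze_subject(wave, config)
        except (ValueError, RuntimeError) as exc:
            failures[wave.subject_id] = str(exc)
            log.warning("subject %s failed: %s", wave.subject_id, exc)
            continue
        phase_parts.append(pdf)
        window_parts.append(wdf)
        failures.update({f"{wave.subject_id}/{k}": v for k, v in fail.items()})
        log.info("analyze %s: %.1f s, %d window failures",
                 wave.subject_id, time.perf_counter() - t0, len(fail))

    if not window_parts:
        raise RuntimeError("no subject could be analyzed: " + json.dumps(failures))
    phase_df = pd.concat(phase_parts, ignore_index=True)
    window_df = pd.concat(window_parts, ignore_index=True)
    report = phase_report(phase_df, window_df, alpha=config.alpha)

    files = []
    for name, df in (("phase_metrics", phase_df), ("window_metrics", window_df),
                     ("percent_changes", report.percent_changes),
                     ("summary", report.summary)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        files.append(p)
    anova_df = pd.DataFrame(
        [{"metric": m, "F": r.f_statistic, "df_between": r.df_between,
          "df_within": r.df_within, "p_value": r.p_value}
         for m, r in report.anova.items()])
    p = outdir / "anova.csv"
    anova_df.to_csv(p, index=False)
    files.append(p)
    for metric, pw in report.tukey.items():
        p = outdir / f"tukey_{metric}.csv"
        pw.p_values.to_csv(p)
        files.append(p)
    if failures:
        p = outdir / "failures.json"
        p.write_text(json.dumps(failures, indent=2))
        files.append(p)
    _write_manifest(outdir, files)
    return outdir, report
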