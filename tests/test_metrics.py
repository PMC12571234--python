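"""Time- and frequency-domain PRV metrics and the per-window pipeline."""

import math
import warnings

import numpy as np
import pytest

from pulsevar.intervals import IntervalSeries, adaptive_filter
from pulsevar.beats import pp_intervals
from pulsevar.io import PressureWaveform, WindowSet
from pulsevar.metrics import (Tachogram, band_power, compute_window_metrics,
                              frequency_domain, power_spectrum, prv_metrics,
                              resample_tachogram, time_domain)
from pulsevar.simulate import (MorphologyParams, generate_beat_times,
                               render_pressure_waveform, hemorrhage_schedule)
from pulsevar.io import segment_windows

from conftest import single_phase_schedule


def make_nn(values, parent_index=None, dt=0.6):
    values = np.asarray(values, dtype=float)
    if parent_index is None:
        parent_index = np.arange(values.size)
    ts = np.arange(values.size) * dt + dt
    return IntervalSeries(values=values, timestamps=ts, kind="NN",
                          rejection_mask=None, parent_index=parent_index)


def direct_stats(values, parent_index):
    """Plain-Python oracle for mean / SDNN / RMSSD (math.fsum arithmetic)."""
    n = len(values)
    mean = math.fsum(values) / n
    sdnn = math.sqrt(math.fsum((v - mean) ** 2 for v in values) / (n - 1))
    sq = [(values[i + 1] - values[i]) ** 2
          for i in range(n - 1) if parent_index[i + 1] - parent_index[i] == 1]
    rmssd = math.sqrt(math.fsum(sq) / len(sq))
    return mean, sdnn, rmssd


class TestTimeDomain:
    def test_constant_series(self):
        mean, sdnn, rmssd = time_domain(make_nn([500.0, 500.0, 500.0]))
        assert (mean, sdnn, rmssd) == (500.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        # deviations (0, 10, -10, 0); successive diffs (10, -20, 10)
        mean, sdnn, rmssd = time_domain(make_nn([500.0, 510.0, 490.0, 500.0]))
        assert mean == pytest.approx(500.0)
        assert sdnn == pytest.approx(math.sqrt(200 / 3), abs=1e-9)   # 8.165
        assert rmssd == pytest.approx(math.sqrt(200), abs=1e-9)      # 14.142

    def test_rmssd_skips_gap_spanning_pairs(self):
        # parent indices 0,1,3,4: the (1,3) pair spans a rejected interval
        nn = make_nn([600.0, 604.0, 700.0, 704.0], parent_index=[0, 1, 3, 4])
        _, _, rmssd = time_domain(nn)
        assert rmssd == pytest.approx(4.0)  # diffs used: (604-600), (704-700)

    def test_matches_direct_arithmetic_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            vals = rng.uniform(300, 1200, n)
            drop = rng.random(n) < 0.1
            parent = np.flatnonzero(~drop)
            if parent.size < 5 or np.count_nonzero(np.diff(parent) == 1) < 2:
                continue
            nn = make_nn(vals[parent], parent_index=parent)
            got = time_domain(nn)
            want = direct_stats(vals[parent], parent)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-9)

    def test_too_short_errors_name_the_metric(self):
        with pytest.raises(ValueError, match="SDNN"):
            time_domain(make_nn([600.0]))
        with pytest.raises(ValueError, match="RMSSD"):
            time_domain(make_nn([600.0, 610.0, 620.0], parent_index=[0, 2, 4]))


class TestTachogram:
    def test_constant_series_resamples_to_zero(self):
        nn = make_nn(np.full(200, 600.0))
        tg = resample_tachogram(nn)
        assert np.max(np.abs(tg.values)) < 1e-9

    def test_sinusoidal_modulation_amplitude_preserved(self):
        t = np.arange(1, 201) * 0.6
        vals = 600.0 + 25.0 * np.sin(2 * np.pi * 0.1 * t)
        nn = IntervalSeries(vals, t, kind="NN")
        tg = resample_tachogram(nn)
        assert np.max(np.abs(tg.values)) == pytest.approx(25.0, rel=0.02)

    def test_short_span_errors(self):
        nn = make_nn(np.full(50, 600.0))  # 30 s span
        with pytest.raises(ValueError, match="60 s"):
            resample_tachogram(nn)


class TestSpectrum:
    def test_zero_tachogram_gives_zero_density(self):
        tg = Tachogram(np.zeros(2048), fs_resample=4.0)
        sd = power_spectrum(tg)
        assert np.all(sd.density == 0)

    def test_sinusoid_parseval(self):
        # variance of a unit sinusoid is 1/2; all of it near 0.1 Hz
        t = np.arange(3600) / 4.0
        tg = Tachogram(np.sin(2 * np.pi * 0.1 * t), fs_resample=4.0)
        sd = power_spectrum(tg)
        assert band_power(sd, (0.08, 0.12)) == pytest.approx(0.5, rel=0.10)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3.0, 4096)
        tg = Tachogram(x - x.mean(), fs_resample=4.0)
        sd = power_spectrum(tg)
        total = np.trapezoid(sd.density, sd.frequencies)
        assert total == pytest.approx(x.var(), rel=0.10)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="short"):
            power_spectrum(Tachogram(np.zeros(64), fs_resample=4.0))


class TestBandPower:
    def _sin_spectrum(self, freq):
        t = np.arange(3600) / 4.0
        tg = Tachogram(np.sin(2 * np.pi * freq * t), fs_resample=4.0)
        return power_spectrum(tg)

    def test_lf_sinusoid_lands_in_lf(self):
        sd = self._sin_spectrum(0.1)
        lf = band_power(sd, (0.04, 0.15))
        hf = band_power(sd, (0.15, 0.40))
        total = band_power(sd, (0.0, 0.40))
        assert lf == pytest.approx(total, rel=0.02)
        assert lf / max(hf, 1e-12) > 50

    def test_hf_sinusoid_lands_in_hf(self):
        sd = self._sin_spectrum(0.3)
        lf = band_power(sd, (0.04, 0.15))
        hf = band_power(sd, (0.15, 0.40))
        assert lf / hf < 0.02

    def test_band_outside_grid_errors(self):
        sd = self._sin_spectrum(0.1)
        with pytest.raises(ValueError, match="outside"):
            band_power(sd, (1.9, 2.5))


class TestFrequencyDomain:
    def test_dual_sinusoid_amplitude_ratio_squared(self):
        sched = single_phase_schedule(900.0, mean_rate=90, a_lf=0.08, f_lf=0.10,
                                      a_hf=0.04, f_hf=0.30, noise_sd=0.005,
                                      seed=31)
        nn = adaptive_filter(pp_intervals(generate_beat_times(sched)))
        lf, hf, total, ratio = frequency_domain(nn)
        assert ratio == pytest.approx(4.0, rel=0.25)
        assert lf + hf <= total * 1.01

    def test_constant_series_ratio_undefined(self):
        nn = make_nn(np.full(200, 600.0))
        with pytest.warns(UserWarning, match="undefined"):
            lf, hf, total, ratio = frequency_domain(nn)
        assert lf == hf == 0.0
        assert math.isnan(ratio)

    def test_deterministic(self, modulated_nn):
        a = frequency_domain(modulated_nn)
        b = frequency_domain(modulated_nn)
        assert a == b

    @pytest.mark.parametrize("freq", [0.05, 0.10, 0.20, 0.35])
    def test_single_modulation_frequency_assigned_to_correct_band(self, freq):
        in_lf = freq <= 0.15
        sched = single_phase_schedule(
            600.0, mean_rate=90,
            a_lf=0.06 if in_lf else 0.0, f_lf=freq if in_lf else 0.10,
            a_hf=0.0 if in_lf else 0.06, f_hf=freq if not in_lf else 0.30,
            noise_sd=0.003, seed=5)
        nn = adaptive_filter(pp_intervals(generate_beat_times(sched)))
        lf, hf, _, _ = frequency_domain(nn)
        correct = lf if in_lf else hf
        assert correct / (lf + hf) >= 0.85

    def test_parseval_total_power_matches_tachogram_variance(self, modulated_nn):
        tg = resample_tachogram(modulated_nn)
        _, _, total, _ = frequency_domain(modulated_nn)
        # total band stops at 0.4 Hz; compare against variance below 0.4 Hz
        sd = power_spectrum(tg)
        full = np.trapezoid(sd.density, sd.frequencies)
        assert full == pytest.approx(tg.values.var(), rel=0.05)


@pytest.fixture(scope="module")
def small_windows():
    sched = hemorrhage_schedule(phase_duration=300.0, subwindow_duration=150.0)
    beats = generate_beat_times(sched)
    wave = render_pressure_waveform(beats, MorphologyParams(), fs=250.0,
                                    duration=sched.total_duration)
    wave.subject_id = "s1"
    _, windows = segment_windows(wave, sched)
    return windows


class TestWindowPipeline:
    def test_table_covers_every_window_and_metric(self, small_windows):
        df, failures = compute_window_metrics(small_windows)
        assert not failures
        assert set(df["group_label"]) == set(small_windows.labels)
        assert df.groupby("group_label")["metric"].count().eq(7).all()

    def test_failed_window_is_labeled_not_fatal(self, small_windows):
        windows = WindowSet(
            windows={**small_windows.windows,
                     99: PressureWaveform(np.full(200 * 250, 80.0), fs=250.0)},
            phases={**small_windows.phases, 99: "baseline"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df, failures = compute_window_metrics(windows)
        assert 99 in failures
        assert set(df["group_label"]) == set(small_windows.labels)

    def test_single_window_equals_manual_stages(self, small_windows):
        from pulsevar.metrics import analyze_segment
        label = small_windows.labels[0]
        wave = small_windows.windows[label]
        df, _ = compute_window_metrics(small_windows)
        manual = analyze_segment(wave)
        got = df[df.group_label == label].set_index("metric")["value"]
        for name, value in manual.as_dict().items():
            assert got[name] == pytest.approx(value, rel=1e-12, nan_ok=True)
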