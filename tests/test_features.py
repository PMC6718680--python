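"""Moving-window statistics, event series, and the curve fits."""
import numpy as np
import pytest

from alphawatch.features import (
    EventSeries,
    TimeSeries,
    baseline_band_features,
    duration_series,
    event_amplitude_series,
    exp_saturation_fit,
    first_occurrence_time,
    group_average_series,
    initial_slope,
    linear_slope_fit,
    occurrence_frequency,
    sliding_proportions,
)
from alphawatch.intervals import IntervalSet
from alphawatch.io_eeg import EEGRecording, REQUIRED_CHANNELS
from alphawatch.segmentation import Segmentation


def _seg(a_pairs=(), ies_pairs=(), span=(0.0, 600.0)):
    return Segmentation(
        consensus_aS=IntervalSet(a_pairs), ies=IntervalSet(ies_pairs), span=span
    )


class TestSlidingProportions:
    def test_full_coverage_is_hundred_percent(self):
        seg = _seg(a_pairs=[(0.0, 600.0)])
        p = sliding_proportions(seg)
        assert np.allclose(p.p_alpha, 100.0)
        assert np.allclose(p.p_hyp, 0.0)

    def test_quarter_overlap_at_window_end(self):
        seg = _seg(a_pairs=[(0.0, 60.0)])
        p = sliding_proportions(seg, window=240.0, step=1.0)
        i = np.searchsorted(p.times, 240.0)
        assert p.p_alpha[i] == pytest.approx(25.0)

    def test_partition_sums_to_hundred_everywhere(self):
        rng = np.random.default_rng(4)
        starts = np.sort(rng.uniform(0, 550, 20))
        a = IntervalSet.coalesce([(s, s + rng.uniform(0.5, 4)) for s in starts[:10]])
        i = IntervalSet.coalesce([(s, s + rng.uniform(1, 5)) for s in starts[10:]])
        seg = Segmentation(consensus_aS=a.difference(i), ies=i, span=(0.0, 600.0))
        p = sliding_proportions(seg)
        assert np.allclose(p.p_alpha + p.p_ies + p.p_hyp, 100.0)
        assert np.all(p.p_alpha >= -1e-9) and np.all(p.p_ies >= -1e-9)


class TestFirstOccurrence:
    def test_never_reached_is_none(self):
        assert first_occurrence_time(np.arange(10.0), np.zeros(10)) is None

    def test_step_crossing_and_boundary_semantics(self):
        t = np.arange(1.0, 601.0)
        p = np.where(t >= 300.0, 6.0, 0.0)
        assert first_occurrence_time(t, p) == 300.0
        p_exact = np.where(t >= 300.0, 5.0, 0.0)
        assert first_occurrence_time(t, p_exact) == 300.0


class TestInitialSlope:
    def test_exact_linear(self):
        t = np.arange(1.0, 601.0)  # seconds
        y = 2.0 * t / 60.0  # 2 % per minute
        assert initial_slope(t, y) == pytest.approx(2.0)

    def test_noisy_linear_recovery_over_seeds(self):
        t = np.arange(1.0, 601.0)
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = 2.0 * t / 60.0 + rng.normal(0, 0.5, t.size)
            errs.append(initial_slope(t, y) - 2.0)
        assert abs(np.mean(errs)) < 0.2

    def test_zero_proportion_gives_zero_slope(self):
        t = np.arange(1.0, 601.0)
        assert initial_slope(t, np.zeros_like(t)) == 0.0


class TestGroupAverage:
    def test_linear_midpoint(self):
        s = EventSeries(times=np.array([0.0, 60.0]), values=np.array([1.0, 3.0]))
        g = group_average_series([s, s], grid_step=1.0, min_patients=1)
        assert np.interp(30.0, g.times, g.values) == pytest.approx(2.0)

    def test_two_identical_patients_equal_either(self):
        s = EventSeries(times=np.array([0.0, 10.0, 20.0]), values=np.array([1.0, 2.0, 1.5]))
        g = group_average_series([s, s], grid_step=1.0, min_patients=1)
        assert np.allclose(g.values, np.interp(g.times, s.times, s.values))

    def test_three_patient_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        series = []
        for _ in range(3):
            t = np.sort(rng.uniform(0, 100, 8))
            v = rng.uniform(0.5, 3.0, 8)
            series.append(EventSeries(times=t, values=v))
        g = group_average_series(series, grid_step=1.0, min_patients=3)
        for tt, vv in zip(g.times, g.values):
            contrib = [
                np.interp(tt, s.times, s.values)
                for s in series
                if s.times[0] <= tt <= s.times[-1]
            ]
            assert len(contrib) == 3
            assert vv == pytest.approx(np.mean(contrib))

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            group_average_series([EventSeries(times=np.array([]), values=np.array([]))])


class TestOccurrenceFrequency:
    def test_hand_count(self):
        seg = _seg(a_pairs=[(100 + 3 * k, 101.5 + 3 * k) for k in range(5)])
        f = occurrence_frequency(seg, w_f=50.0, step=10.0)
        i = np.searchsorted(f.times, 110.0)
        assert f.values[i] == pytest.approx(5 / (50 / 60.0))

    def test_no_events_is_zero(self):
        f = occurrence_frequency(_seg())
        assert np.allclose(f.values, 0.0)

    def test_translation_equivariance(self):
        pairs = [(100 + 7 * k, 102 + 7 * k) for k in range(10)]
        f1 = occurrence_frequency(_seg(pairs), step=10.0)
        shifted = [(s + 10.0, e + 10.0) for s, e in pairs]
        f2 = occurrence_frequency(_seg(shifted), step=10.0)
        assert np.allclose(f1.values[5:-5], f2.values[6:-4])


class TestEventAmplitude:
    FS = 64.0

    def test_constant_magnitude(self):
        y = np.full(int(10 * self.FS), 3.0)
        es = event_amplitude_series(y, self.FS, IntervalSet([(2.0, 5.0)]))
        assert es.values[0] == pytest.approx(3.0)

    def test_rectified_sinusoid_mean(self):
        t = np.arange(0, 10, 1 / 640.0)
        y = np.abs(5.0 * np.sin(2 * np.pi * 10 * t))
        es = event_amplitude_series(y, 640.0, IntervalSet([(2.0, 2.1)]))  # one full cycle
        assert es.values[0] == pytest.approx(2 * 5.0 / np.pi, rel=0.02)

    def test_matches_dense_numerical_integration(self):
        rng = np.random.default_rng(2)
        y = np.abs(rng.standard_normal(int(20 * self.FS)))
        iv = IntervalSet([(1.234, 3.456), (7.0, 11.5)])
        es = event_amplitude_series(y, self.FS, iv)
        t = np.arange(y.size) / self.FS
        for (s, e), got in zip(iv, es.values):
            dense_t = np.linspace(s, e, 20001)
            dense = np.interp(dense_t, t, y)
            want = np.trapezoid(dense, dense_t) / (e - s)
            assert got == pytest.approx(want, rel=0.01)

    def test_zero_length_event_rejected(self):
        with pytest.raises(ValueError):
            IntervalSet([(1.0, 1.0)])


class TestFits:
    def test_exact_line(self):
        t = np.arange(0.0, 600.0)
        series = TimeSeries(times=t, values=0.16 * t / 60.0 + 1.0)
        slope, intercept = linear_slope_fit(series)
        assert slope == pytest.approx(0.16)
        assert intercept == pytest.approx(1.0)

    def test_constant_series_zero_slope(self):
        series = TimeSeries(times=np.arange(0.0, 300.0), values=np.full(300, 2.0))
        slope, _ = linear_slope_fit(series)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_recovery(self):
        t = np.arange(0.0, 600.0)
        devs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            series = TimeSeries(times=t, values=0.5 * t / 60.0 + rng.normal(0, 0.3, t.size))
            slope, _ = linear_slope_fit(series)
            devs.append(slope - 0.5)
        assert abs(np.mean(devs)) < 0.02

    def test_exponential_saturation_self_consistency(self):
        t = np.arange(0.0, 35 * 60.0, 10.0)
        y = 8.3 * (1 - np.exp(-(t / 60.0) / 1.9))
        f_max, tau, r2 = exp_saturation_fit(TimeSeries(times=t, values=y))
        assert f_max == pytest.approx(8.3, rel=0.01)
        assert tau == pytest.approx(1.9, rel=0.01)
        assert r2 > 0.999

    def test_constant_series_degenerates_gracefully(self):
        t = np.arange(0.0, 600.0, 10.0)
        f_max, tau, _ = exp_saturation_fit(TimeSeries(times=t, values=np.full(t.size, 4.0)))
        assert f_max == pytest.approx(4.0)
        assert tau <= 0.01

    def test_noisy_plateau_recovery_over_seeds(self):
        t = np.arange(0.0, 35 * 60.0, 10.0)
        rec = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = 8.3 * (1 - np.exp(-(t / 60.0) / 1.9)) + rng.normal(0, 0.5, t.size)
            f_max, _, _ = exp_saturation_fit(TimeSeries(times=t, values=y))
            rec.append(f_max)
        assert np.mean(rec) == pytest.approx(8.3, rel=0.10)


class TestBaselineBands:
    def _rec(self, freq, fs=128.0):
        t = np.arange(int(120 * fs)) / fs
        x = 20.0 * np.sin(2 * np.pi * freq * t)
        return EEGRecording(REQUIRED_CHANNELS, fs, np.tile(x, (4, 1)))

    def test_alpha_dominant_ratio(self):
        _, ratio = baseline_band_features(self._rec(10.0), (0.0, 120.0))
        assert ratio >= 10.0

    def test_delta_dominant_ratio(self):
        _, ratio = baseline_band_features(self._rec(2.0), (0.0, 120.0))
        assert ratio <= 0.1

    def test_white_noise_ratio_near_bandwidth_ratio(self):
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fs = 128.0
            x = rng.standard_normal(int(120 * fs))
            rec = EEGRecording(REQUIRED_CHANNELS, fs, np.tile(x, (4, 1)))
            _, r = baseline_band_features(rec, (0.0, 120.0))
            ratios.append(r)
        assert np.mean(ratios) == pytest.approx(6.0 / 4.5, rel=0.5)


class TestDurationSeries:
    def test_events_anchor_at_starts(self):
        seg = _seg(a_pairs=[(10.0, 11.5), (40.0, 44.0)])
        d = duration_series(seg)
        assert list(d.times) == [10.0, 40.0]
        assert list(d.values) == [1.5, 4.0]
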