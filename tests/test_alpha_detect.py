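"""The five detector steps against closed forms and brute-force oracles."""
import numpy as np
import pytest

from alphawatch.alpha_detect import (
    AlphaBandSignal,
    amplification_kernel,
    band_filter_wavelet,
    build_enhancement,
    consensus_merge,
    detect_alpha_suppressions,
    morph_repair,
    swing_envelope,
    threshold_suppressions,
)
from alphawatch.intervals import IntervalSet
from alphawatch.io_eeg import EEGRecording, REQUIRED_CHANNELS

FS = 64.0


def _sine(freq, duration=20.0, amp=1.0, fs=FS):
    t = np.arange(0.0, duration, 1.0 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandFilter:
    def test_in_band_energy_kept(self):
        x = _sine(12.0)
        out = band_filter_wavelet(x, FS).values
        assert out.var() >= 0.60 * x.var()

    def test_out_of_band_energy_rejected(self):
        x = _sine(2.0)
        out = band_filter_wavelet(x, FS).values
        assert out.var() <= 0.05 * x.var()

    def test_zero_signal_and_bad_rate(self):
        assert np.allclose(band_filter_wavelet(np.zeros(256), FS).values, 0.0)
        with pytest.raises(ValueError):
            band_filter_wavelet(np.zeros(256), 100.0)

    def test_output_aligns_with_input_length(self):
        x = np.random.default_rng(0).standard_normal(1001)
        assert band_filter_wavelet(x, FS).values.size == 1001


def brute_force_swing(x, fs, w=1.0):
    """Oracle: enumerate extrema pairs per window, O(n^2)."""
    n = x.size
    ext = []
    for i in range(1, n - 1):
        if (x[i] - x[i - 1]) * (x[i + 1] - x[i]) < 0:
            ext.append(i)
    pairs = []
    for a, b in zip(ext[:-1], ext[1:]):
        if x[a] * x[b] < 0:
            pairs.append((a / fs, b / fs, abs(x[a] - x[b])))
    amp = np.zeros(n)
    for k in range(n):
        t = k / fs
        ds = [d for (ta, tb, d) in pairs if ta >= t - w / 2 and tb <= t + w / 2]
        if ds:
            amp[k] = np.mean(ds)
    return amp


class TestSwingEnvelope:
    def test_sinusoid_swing_is_twice_amplitude(self):
        x = AlphaBandSignal(FS, _sine(10.0, amp=10.0))
        env = swing_envelope(x)
        mid = env.values[int(2 * FS): int(18 * FS)]
        assert np.mean(mid) == pytest.approx(20.0, rel=0.05)

    def test_zero_signal_gives_zero_envelope(self):
        env = swing_envelope(AlphaBandSignal(FS, np.zeros(512)))
        assert np.allclose(env.values, 0.0)

    def test_matches_brute_force_oracle_on_random_signal(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(int(5 * FS))
        env = swing_envelope(AlphaBandSignal(FS, x))
        oracle = brute_force_swing(x, FS)
        assert np.allclose(env.values, oracle, atol=1e-9)


class TestKernel:
    def test_closed_forms(self):
        assert amplification_kernel(0.0) == pytest.approx(1.0)
        assert amplification_kernel(1.0) == pytest.approx(1.72)

    def test_argmax_at_t_b(self):
        g = np.arange(0.0, 10.0, 0.001)
        k = amplification_kernel(g)
        assert abs(g[np.argmax(k)] - 1.0) <= 0.01

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            amplification_kernel(-0.5)


class TestEnhancement:
    def test_flat_envelope_places_no_kernels(self):
        s = AlphaBandSignal(FS, _sine(10.0, duration=10.0))
        env = swing_envelope(AlphaBandSignal(FS, np.zeros(s.values.size)))
        prof = build_enhancement(env, s)
        assert prof.kernel_times.size == 0
        assert np.allclose(prof.phi, 1.0)
        assert np.array_equal(prof.s_phi, s.values)

    @pytest.mark.parametrize("peak, expect_kernel", [(2.0, True), (1.3, False)])
    def test_burst_ratio_rule(self, peak, expect_kernel):
        # hand-built envelope: baseline 1, one triangular bump to `peak`
        n = int(20 * FS)
        amp = np.ones(n)
        c = n // 2
        half = int(2 * FS)
        bump = np.concatenate([
            np.linspace(0, peak - 1.0, half), np.linspace(peak - 1.0, 0, half)
        ])
        amp[c - half: c + half] += bump
        env = swing_envelope(AlphaBandSignal(FS, np.zeros(n)))
        env.values[:] = amp
        prof = build_enhancement(env, AlphaBandSignal(FS, np.zeros(n)))
        assert (prof.kernel_times.size > 0) == expect_kernel
        if expect_kernel:
            assert prof.kernel_times.size == 1
            assert abs(prof.kernel_times[0] - c / FS) < 0.1

    def test_phi_never_below_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(30 * FS))
        s = AlphaBandSignal(FS, x)
        prof = build_enhancement(swing_envelope(s), s)
        assert np.all(prof.phi >= 1.0 - 1e-12)


class TestThreshold:
    def _profile(self, mag):
        s = AlphaBandSignal(FS, mag)
        prof = build_enhancement(swing_envelope(AlphaBandSignal(FS, np.zeros(mag.size))), s)
        return prof

    def test_deep_dip_detected_with_boundaries(self):
        # 100 uV carrier except 10 uV on [10, 14) s
        x = _sine(10.0, duration=60.0, amp=100.0)
        dip = slice(int(10 * FS), int(14 * FS))
        x[dip] *= 0.10
        raw = threshold_suppressions(self._profile(x), norm_window=120.0)
        assert len(raw) == 1
        (s, e), = list(raw)
        assert abs(s - 10.0) <= 0.5 and abs(e - 14.0) <= 0.5

    def test_constant_signal_has_no_suppressions(self):
        x = _sine(10.0, duration=60.0, amp=50.0)
        assert len(threshold_suppressions(self._profile(x))) == 0

    def test_dip_above_threshold_ratio_not_detected(self):
        x = _sine(10.0, duration=60.0, amp=100.0)
        x[int(10 * FS): int(14 * FS)] *= 0.30  # 0.30 > T = 0.25
        assert len(threshold_suppressions(self._profile(x), norm_window=120.0)) == 0

    def test_all_zero_signal_is_one_full_span_suppression(self):
        raw = threshold_suppressions(self._profile(np.zeros(int(30 * FS))))
        assert len(raw) == 1
        (s, e), = list(raw)
        assert s == 0.0 and e == pytest.approx(30.0, abs=1 / FS)

    def test_detection_invariant_to_global_rescaling(self):
        x = _sine(10.0, duration=60.0, amp=100.0)
        x[int(20 * FS): int(24 * FS)] *= 0.1
        a = threshold_suppressions(self._profile(x))
        b = threshold_suppressions(self._profile(1000.0 * x))
        assert a == b


class TestMorphology:
    def test_gap_bridging(self):
        out = morph_repair(IntervalSet([(0, 2), (3.5, 5)]))
        assert list(out) == [pytest.approx((0.2, 4.8))]

    def test_short_interval_removed(self):
        assert len(morph_repair(IntervalSet([(10, 10.3)]))) == 0

    def test_empty_set(self):
        assert len(morph_repair(IntervalSet())) == 0

    def test_isolated_duration_law_and_zero_identity(self):
        # surviving isolated interval shrinks by 2*(erode - dilate)
        out = morph_repair(IntervalSet([(10.0, 15.0)]))
        assert out.durations[0] == pytest.approx(5.0 - 2 * 0.2)
        same = morph_repair(out, dilate=0.0, erode=0.0)
        assert same == out


class TestConsensus:
    def test_all_channels_agree(self):
        sets = [IntervalSet([(5, 8)])] * 4
        assert list(consensus_merge(sets)) == [(5, 8)]

    def test_single_channel_is_discarded(self):
        sets = [IntervalSet([(5, 8)])] + [IntervalSet()] * 3
        assert len(consensus_merge(sets)) == 0

    def test_two_channel_overlap_matches_boolean_oracle(self):
        sets = [
            IntervalSet([(5, 8)]),
            IntervalSet([(6, 9)]),
            IntervalSet(),
            IntervalSet(),
        ]
        assert list(consensus_merge(sets)) == [(6, 8)]

    def test_short_coincidences_dropped(self):
        sets = [IntervalSet([(5, 5.05)]), IntervalSet([(5, 5.05)]), IntervalSet(), IntervalSet()]
        assert len(consensus_merge(sets)) == 0


class TestDetectOrchestration:
    def _recording_with_collapse(self):
        rng = np.random.default_rng(5)
        fs = 128.0
        n = int(120 * fs)
        t = np.arange(n) / fs
        data = []
        for _ in range(4):
            alpha = 14.0 * np.sin(2 * np.pi * 10 * t)
            mask = (t >= 60.0) & (t < 63.0)
            alpha[mask] *= 0.08
            data.append(alpha + 2.0 * rng.standard_normal(n))
        return EEGRecording(REQUIRED_CHANNELS, fs, np.array(data))

    def test_planted_collapse_recovered(self):
        rec = self._recording_with_collapse()
        _, consensus = detect_alpha_suppressions(rec)
        assert len(consensus) >= 1
        best = max(
            (min(e, 63.0) - max(s, 60.0), (s, e)) for s, e in consensus
        )
        inter = best[0]
        s, e = best[1]
        union = max(e, 63.0) - min(s, 60.0)
        assert inter / union >= 0.6

    def test_continuous_alpha_yields_no_events(self):
        fs = 128.0
        t = np.arange(int(120 * fs)) / fs
        x = 14.0 * np.sin(2 * np.pi * 10 * t)
        rec = EEGRecording(REQUIRED_CHANNELS, fs, np.tile(x, (4, 1)))
        _, consensus = detect_alpha_suppressions(rec)
        assert len(consensus) == 0

    def test_deterministic_for_fixed_input(self):
        rec = self._recording_with_collapse()
        per1, c1 = detect_alpha_suppressions(rec)
        per2, c2 = detect_alpha_suppressions(rec)
        assert c1 == c2
        assert all(per1[ch] == per2[ch] for ch in per1)
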