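"""Morlet decomposition and the median-threshold burst detector."""

import numpy as np
import pytest

from tapburst.core import Recording
from tapburst.detection import (
    BurstMask,
    DetectionParams,
    TFPower,
    detect_bursts,
    extract_segments,
    tf_decompose,
    _runs,
)
from tapburst.validation import brute_force_detect


def _sine_recording(freq=20.0, amp=1.0, dur=10.0, fs=1000.0, n_ch=1):
    t = np.arange(int(dur * fs)) / fs
    sig = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(sig, fs, [f"c{i}" for i in range(n_ch)])


class TestTFDecompose:
    def test_sinusoid_ridge_at_own_frequency(self):
        tf = tf_decompose(_sine_recording(freq=20.0))
        mean_p = np.array([tf.power[0, i, tf.valid[i]].mean() for i in range(tf.freqs.size)])
        assert tf.freqs[np.argmax(mean_p)] == 20.0
        # stationary tone: power approximately constant away from edges
        i20 = int(np.argmax(mean_p))
        trace = tf.power[0, i20, tf.valid[i20]]
        assert trace.std() / trace.mean() < 0.05

    def test_zero_signal_zero_power(self):
        rec = Recording(np.zeros((1, 5000)), 1000.0, ["a"])
        tf = tf_decompose(rec)
        assert np.allclose(tf.power, 0.0)

    def test_quadratic_amplitude_scaling(self):
        p1 = tf_decompose(_sine_recording(amp=1.0)).power
        p2 = tf_decompose(_sine_recording(amp=2.0)).power
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-6, atol=1e-12)

    def test_nyquist_and_short_recording_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tf_decompose(_sine_recording(fs=50.0))
        with pytest.raises(ValueError, match="shorter"):
            tf_decompose(_sine_recording(dur=0.5))


def _toy_tf(power_1d, freq=20.0, fs=1000.0):
    p = np.asarray(power_1d, float)[np.newaxis, np.newaxis, :]
    return TFPower(power=p, freqs=np.array([freq]), fs=fs)


class TestDetectBursts:
    def test_stationary_tone_yields_no_bursts(self):
        tf = tf_decompose(_sine_recording())
        mask = detect_bursts(tf)
        assert not mask.series.any()

    def test_two_cycle_rule_on_toy_trace(self):
        # median 1 → threshold 6; 60 ms run < 100 ms (2 cycles at 20 Hz)
        p = np.ones(960)
        p[400:460] = 50.0
        mask = detect_bursts(_toy_tf(p))
        assert not mask.series.any()
        # 120 ms run survives
        p = np.ones(900)
        p[400:520] = 50.0
        mask = detect_bursts(_toy_tf(p))
        segs = extract_segments(mask)
        assert len(segs) == 1
        assert segs[0].duration_s == pytest.approx(0.120)

    def test_channel_specificity(self, rng):
        # bursts injected in channel 0 only → channel 1 series stays empty
        p = np.ones((2, 1, 2000))
        p[0, 0, 500:700] = 50.0
        tf = TFPower(power=p, freqs=np.array([20.0]), fs=1000.0)
        mask = detect_bursts(tf)
        assert mask.series[0].any() and not mask.series[1].any()

    def test_strict_inequality_at_threshold(self):
        p = np.ones(1000)
        p[100:300] = 6.0  # exactly 6× median of 1 → not greater
        mask = detect_bursts(_toy_tf(p))
        assert not mask.series.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        n_ch, n_f, n_t = 2, 3, 800
        power = rng.exponential(1.0, (n_ch, n_f, n_t))
        power[rng.uniform(size=power.shape) < 0.05] *= 20
        freqs = np.array([14.0, 20.0, 28.0])
        valid = rng.uniform(size=(n_f, n_t)) > 0.03
        tf = TFPower(power=power, freqs=freqs, fs=500.0, valid=valid)
        got = detect_bursts(tf)
        ref_tf, ref_series = brute_force_detect(power, freqs, 500.0, valid)
        np.testing.assert_array_equal(got.tf_mask, ref_tf)
        np.testing.assert_array_equal(got.series, ref_series)

    def test_threshold_and_duration_monotonicity(self, rng):
        power = rng.exponential(1.0, (1, 2, 1500))
        power[rng.uniform(size=power.shape) < 0.08] *= 15
        tf = TFPower(power=power, freqs=np.array([15.0, 25.0]), fs=500.0)
        base = detect_bursts(tf, DetectionParams(threshold_factor=4.0, min_cycles=1.0))
        stricter = detect_bursts(tf, DetectionParams(threshold_factor=6.0, min_cycles=1.0))
        longer = detect_bursts(tf, DetectionParams(threshold_factor=4.0, min_cycles=2.0))
        assert not (stricter.tf_mask & ~base.tf_mask).any()
        assert not (longer.tf_mask & ~base.tf_mask).any()

    def test_scale_invariance(self, rng):
        rec = Recording(rng.standard_normal((2, 8000)), 1000.0, ["a", "b"])
        rec2 = Recording(rec.signal * np.array([[3.7], [0.2]]), 1000.0, ["a", "b"])
        m1 = detect_bursts(tf_decompose(rec))
        m2 = detect_bursts(tf_decompose(rec2))
        np.testing.assert_array_equal(m1.tf_mask, m2.tf_mask)

    def test_clearly_suprathreshold_atoms_are_recovered(self):
        # atoms whose peak power is far above 6× the background median and
        # whose duration is well over 2 cycles overlap a detected segment
        from tapburst.synth import SynthConfig, gen_session

        cfg = SynthConfig(
            n_channels=2, duration_s=120.0, snr=30.0,
            burst_duration_median_s=0.3, burst_duration_sigma=0.1, seed=42,
        )
        rec, _, gt = gen_session(cfg)
        mask = detect_bursts(tf_decompose(rec))
        n_hit = 0
        for row in gt.atoms.itertuples(index=False):
            i0 = int(row.onset_s * 1000)
            i1 = int((row.onset_s + row.duration_s) * 1000)
            n_hit += bool(mask.series[int(row.channel), i0:i1].any())
        assert n_hit / len(gt.atoms) >= 0.9


class TestExtractSegments:
    def test_run_length_encoding(self):
        series = np.zeros((1, 1000), dtype=bool)
        series[0, 100:220] = True
        series[0, 500:800] = True
        mask = BurstMask(
            tf_mask=series[:, np.newaxis, :], series=series, freqs=np.array([20.0]), fs=1000.0
        )
        segs = extract_segments(mask)
        assert [(s.onset_s, s.offset_s) for s in segs] == [(0.1, 0.22), (0.5, 0.8)]
        assert segs[0].duration_s == pytest.approx(0.12)

    def test_empty_series(self):
        series = np.zeros((1, 100), dtype=bool)
        mask = BurstMask(
            tf_mask=series[:, np.newaxis, :], series=series, freqs=np.array([20.0]), fs=1000.0
        )
        assert extract_segments(mask) == []

    def test_overlapping_frequencies_collapse_to_one_segment(self):
        tf_mask = np.zeros((1, 2, 400), dtype=bool)
        tf_mask[0, 0, 0:200] = True  # 15 Hz [0, 200) ms
        tf_mask[0, 1, 150:300] = True  # 25 Hz [150, 300) ms
        series = tf_mask.any(axis=1)
        mask = BurstMask(tf_mask=tf_mask, series=series, freqs=np.array([15.0, 25.0]), fs=1000.0)
        segs = extract_segments(mask)
        assert len(segs) == 1
        assert (segs[0].onset_s, segs[0].offset_s) == (0.0, 0.3)

    def test_peak_comes_from_suprathreshold_support(self):
        tf_mask = np.zeros((1, 2, 100), dtype=bool)
        tf_mask[0, 0, 10:40] = True
        power = np.ones((1, 2, 100))
        power[0, 0, 20] = 9.0
        power[0, 1, 25] = 50.0  # larger, but not suprathreshold
        series = tf_mask.any(axis=1)
        mask = BurstMask(tf_mask=tf_mask, series=series, freqs=np.array([15.0, 25.0]), fs=100.0)
        tf = TFPower(power=power, freqs=np.array([15.0, 25.0]), fs=100.0)
        seg = extract_segments(mask, tf)[0]
        assert seg.peak_power == 9.0 and seg.peak_freq == 15.0
        assert seg.peak_time_s == pytest.approx(0.2)


def test_runs_helper_edges():
    assert _runs(np.array([True, True, False, True])) == [(0, 2), (3, 4)]
    assert _runs(np.zeros(5, dtype=bool)) == []
    assert _runs(np.ones(3, dtype=bool)) == [(0, 3)]
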