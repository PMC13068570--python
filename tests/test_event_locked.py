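"""Touch-locked raster, BPI, extrema, and touch↔burst latencies."""

import numpy as np
import pytest

from tapburst.core import EventTrain
from tapburst.detection import BurstSegment
from tapburst.event_locked import (
    BPISeries,
    BurstRaster,
    bpi_extrema,
    compute_bpi,
    epoch_bursts,
    touch_burst_latencies,
)


class TestEpochBursts:
    def test_index_arithmetic(self):
        series = np.zeros((1, 10000), dtype=bool)
        series[0, 2000:8001] = True  # exactly the epoch of an event at 5.0 s
        raster = epoch_bursts(series, EventTrain([5.0]), fs=1000.0)
        assert raster.data.shape == (1, 1, 6001)
        assert raster.data.all()
        assert raster.times[0] == pytest.approx(-3.0)
        assert raster.times[-1] == pytest.approx(3.0)

    def test_boundary_trial_dropped(self):
        series = np.zeros((1, 10000), dtype=bool)
        raster = epoch_bursts(series, EventTrain([1.0, 5.0]), fs=1000.0)
        assert raster.n_trials == 1 and raster.n_dropped == 1

    def test_all_on_series(self):
        series = np.ones((2, 10000), dtype=bool)
        raster = epoch_bursts(series, EventTrain([4.0, 5.0]), fs=1000.0)
        assert raster.data.all()

    def test_seam_crossing_dropped(self):
        series = np.zeros((1, 12000), dtype=bool)
        raster = epoch_bursts(
            series, EventTrain([5.0, 8.0]), fs=1000.0, seam_samples=np.array([4000])
        )
        # the event at 5.0 s spans the seam at 4.0 s and is dropped
        assert raster.n_trials == 1 and raster.n_dropped == 1

    def test_no_usable_trials_errors(self):
        series = np.zeros((1, 1000), dtype=bool)
        with pytest.raises(ValueError, match="usable"):
            epoch_bursts(series, EventTrain([0.5]), fs=1000.0)


class TestComputeBPI:
    def test_identical_all_on_trials(self):
        raster = BurstRaster(np.ones((1, 4, 11), dtype=bool), (-0.5, 0.5), 10.0)
        bpi = compute_bpi(raster)
        assert np.all(bpi.raw == 1.0)
        assert bpi.baseline[0] == 1.0
        assert np.all(bpi.bpi == 0.0)

    def test_hand_computed_columns(self):
        data = np.zeros((1, 3, 5), dtype=bool)
        # column sums 0,1,2,3,3
        data[0, :, 1] = [True, False, False]
        data[0, :, 2] = [True, True, False]
        data[0, :, 3] = [True, True, True]
        data[0, :, 4] = [True, True, True]
        raster = BurstRaster(data, (0.0, 0.4), 10.0)
        bpi = compute_bpi(raster)
        np.testing.assert_allclose(bpi.raw[0], [0, 1 / 3, 2 / 3, 1, 1])
        assert bpi.baseline[0] == pytest.approx(2 / 3)
        np.testing.assert_allclose(bpi.bpi[0], [-2 / 3, -1 / 3, 0, 1 / 3, 1 / 3])

    def test_raw_bounded(self, rng):
        data = rng.uniform(size=(3, 40, 21)) < 0.2
        bpi = compute_bpi(BurstRaster(data, (-1.0, 1.0), 10.0))
        assert np.all((bpi.raw >= 0) & (bpi.raw <= 1))

    def test_single_trial_identity(self, rng):
        trace = rng.uniform(size=31) < 0.3
        data = np.tile(trace, (1, 5, 1))
        bpi = compute_bpi(BurstRaster(data, (-1.5, 1.5), 10.0))
        np.testing.assert_allclose(bpi.bpi[0], trace - np.median(trace))

    def test_shift_equivariance(self, rng):
        series = (rng.uniform(size=(1, 20000)) < 0.1).astype(bool)
        ev = EventTrain([6.0, 9.0, 12.0])
        shift = 2.0
        shifted = np.roll(series, int(shift * 1000), axis=1)
        b1 = compute_bpi(epoch_bursts(series, ev, 1000.0))
        b2 = compute_bpi(
            epoch_bursts(shifted, EventTrain(ev.times + shift), 1000.0)
        )
        np.testing.assert_array_equal(b1.bpi, b2.bpi)


class TestExtrema:
    def _bpi(self, vals, fs=10.0):
        vals = np.atleast_2d(np.asarray(vals, float))
        n = vals.shape[1]
        times = -1.0 + np.arange(n) / fs
        return BPISeries(bpi=vals, raw=vals, baseline=np.zeros(vals.shape[0]), times=times, fs=fs)

    def test_flat_zero_tie_break_first_sample(self):
        bpi = self._bpi(np.zeros(21))
        ext = bpi_extrema(bpi)
        assert ext.min_value[0] == 0.0 and ext.max_value[0] == 0.0
        assert ext.min_latency_s[0] == pytest.approx(-1.0)
        assert ext.max_latency_s[0] == pytest.approx(-1.0)

    def test_single_dip_and_peak(self):
        vals = np.zeros(21)
        vals[7] = -0.1  # t = -0.3
        vals[15] = 0.2  # t = +0.5
        ext = bpi_extrema(self._bpi(vals))
        assert ext.min_value[0] == pytest.approx(-0.1)
        assert ext.min_latency_s[0] == pytest.approx(-0.3)
        assert ext.max_value[0] == pytest.approx(0.2)
        assert ext.max_latency_s[0] == pytest.approx(0.5)

    def test_window_restriction(self):
        fs = 10.0
        n = 61  # −3..3 s
        vals = np.zeros(n)
        vals[0] = -5.0  # outside −1..1 window
        vals[35] = -0.2  # t = +0.5
        times = -3.0 + np.arange(n) / fs
        bpi = BPISeries(np.atleast_2d(vals), np.atleast_2d(vals), np.zeros(1), times, fs)
        ext = bpi_extrema(bpi, (-1.0, 1.0))
        assert ext.min_value[0] == pytest.approx(-0.2)


class TestTouchBurstLatencies:
    SEGS = [
        BurstSegment("a", 1.0, 1.2, 1, 20, 1.1),
        BurstSegment("a", 2.0, 2.3, 1, 20, 2.1),
    ]

    def test_between_bursts(self):
        out = touch_burst_latencies(self.SEGS, EventTrain([1.5]), ["a"])
        assert out["a"]["touch_to_onset_s"][0] == pytest.approx(0.5)
        assert out["a"]["offset_to_touch_s"][0] == pytest.approx(0.3)

    def test_inside_burst_skips_ongoing(self):
        out = touch_burst_latencies(self.SEGS, EventTrain([1.1]), ["a"])
        # next onset is the NEXT burst (2.0), not the ongoing one
        assert out["a"]["touch_to_onset_s"][0] == pytest.approx(0.9)
        # no completed burst before → sentinel
        assert np.isnan(out["a"]["offset_to_touch_s"][0])

    def test_no_bursts_sentinels(self):
        out = touch_burst_latencies([], EventTrain([1.0, 2.0]), ["a"])
        assert np.isnan(out["a"]["touch_to_onset_s"]).all()
        assert np.isnan(out["a"]["median_touch_to_onset_s"])
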