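"""Containers, native I/O, the 30 s inactivity filter, and masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tapburst.core import (
    EventTrain,
    Recording,
    SegmentMask,
    ValidationError,
    apply_mask,
    inactive_segment_mask,
    read_events,
    read_recording,
    write_events,
    write_recording,
)


class TestRecording:
    def test_header_round_trip(self, tmp_path, rng):
        rec = Recording(rng.standard_normal((2, 1000)), fs=1000.0, channel_labels=["a", "b"])
        assert rec.duration == pytest.approx(1.0)
        write_recording(tmp_path / "r.tsv", rec)
        back = read_recording(tmp_path / "r.tsv", "native")
        assert back.fs == 1000.0
        assert back.channel_labels == ["a", "b"]
        np.testing.assert_allclose(back.signal, rec.signal, rtol=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(fs=0.0, channel_labels=["a", "b"]),
            dict(fs=100.0, channel_labels=["a"]),
            dict(fs=100.0, channel_labels=["a", "a"]),
        ],
    )
    def test_invariant_violations(self, kwargs, rng):
        with pytest.raises(ValidationError):
            Recording(rng.standard_normal((2, 50)), **kwargs)

    def test_non_finite_samples_named(self):
        sig = np.zeros((2, 10))
        sig[1, 3] = np.nan
        with pytest.raises(ValidationError, match="b.*3"):
            Recording(sig, fs=10.0, channel_labels=["a", "b"])

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_recording(tmp_path / "x.tsv", "matlab")


class TestReadEvents:
    def test_sort_and_dedupe(self, tmp_path):
        (tmp_path / "e.csv").write_text("0.5\n0.2\n0.2\n")
        ev, n_dup = read_events(tmp_path / "e.csv")
        np.testing.assert_allclose(ev.times, [0.2, 0.5])
        assert n_dup == 1

    def test_empty_file_is_valid(self, tmp_path):
        (tmp_path / "e.csv").write_text("")
        ev, n_dup = read_events(tmp_path / "e.csv")
        assert len(ev) == 0 and n_dup == 0

    def test_non_numeric_row_reports_line(self, tmp_path):
        (tmp_path / "e.csv").write_text("1.0\noops\n2.0\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_events(tmp_path / "e.csv")

    def test_header_and_app_label_column(self, tmp_path):
        (tmp_path / "e.csv").write_text("time_s,app_label\n3.0,mail\n1.0,maps\n")
        ev, _ = read_events(tmp_path / "e.csv")
        np.testing.assert_allclose(ev.times, [1.0, 3.0])

    def test_random_timestamps_strictly_increasing(self, tmp_path, rng):
        times = rng.uniform(0, 1000, 1000)
        write_events(tmp_path / "e.csv", EventTrain(np.unique(times)))
        ev, _ = read_events(tmp_path / "e.csv")
        assert np.all(np.diff(ev.times) > 0)


def _brute_force_removed(events, span, thr, n_grid=2000):
    """Literal per-point evaluation of the inactivity rule."""
    ts = np.linspace(span[0], span[1], n_grid, endpoint=False)
    removed = []
    for t in ts:
        prev = events[events <= t]
        nxt = events[events >= t]
        d_prev = t - prev[-1] if prev.size else np.inf
        d_next = nxt[0] - t if nxt.size else np.inf
        removed.append(d_prev > thr and d_next > thr)
    return ts, np.array(removed)


class TestInactivityFilter:
    def test_single_gap(self):
        mask = inactive_segment_mask(EventTrain([10.0, 100.0]), (0.0, 110.0), 30.0)
        assert mask.keep_intervals == [(0.0, 40.0), (70.0, 110.0)]

    def test_dense_events_keep_everything(self):
        ev = EventTrain(np.arange(0.0, 100.0, 5.0))
        mask = inactive_segment_mask(ev, (0.0, 100.0), 30.0)
        assert mask.total_kept == pytest.approx(100.0)

    def test_no_events_removes_everything(self):
        with pytest.warns(UserWarning):
            mask = inactive_segment_mask(EventTrain([]), (0.0, 100.0), 30.0)
        assert mask.keep_intervals == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_point_rule(self, seed):
        rng = np.random.default_rng(seed)
        events = np.unique(rng.uniform(0, 500, rng.integers(1, 15)))
        mask = inactive_segment_mask(EventTrain(events), (0.0, 500.0), 30.0)
        ts, removed = _brute_force_removed(events, (0.0, 500.0), 30.0)
        kept_rule = ~removed
        kept_mask = np.array([mask.contains(t) for t in ts])
        # allow disagreement only exactly at interval boundaries
        assert np.mean(kept_rule != kept_mask) < 2 / ts.size

    def test_idempotent(self):
        ev = EventTrain([10.0, 100.0, 300.0])
        m1 = inactive_segment_mask(ev, (0.0, 400.0), 30.0)
        # re-apply the rule on each kept interval: nothing further removed
        for a, b in m1.keep_intervals:
            m2 = inactive_segment_mask(ev.restrict(a - 30, b + 30), (a, b), 30.0)
            assert m2.total_kept == pytest.approx(b - a)


class TestApplyMask:
    def test_concatenation_and_seam(self, rng):
        rec = Recording(rng.standard_normal((1, 30)), fs=10.0, channel_labels=["a"])
        masked, imap = apply_mask(rec, SegmentMask([(0.0, 1.0), (2.0, 3.0)]))
        assert masked.n_samples == 20
        assert list(imap.seams) == [10]
        np.testing.assert_array_equal(masked.signal[:, 10:], rec.signal[:, 20:30])

    def test_full_span_identity(self, rng):
        rec = Recording(rng.standard_normal((2, 30)), fs=10.0, channel_labels=["a", "b"])
        masked, imap = apply_mask(rec, SegmentMask([(0.0, 3.0)]))
        np.testing.assert_array_equal(masked.signal, rec.signal)
        assert imap.seams.size == 0

    def test_event_time_translation(self, rng):
        rec = Recording(rng.standard_normal((1, 30)), fs=10.0, channel_labels=["a"])
        _, imap = apply_mask(rec, SegmentMask([(0.0, 1.0), (2.0, 3.0)]))
        assert imap.map_times(np.array([2.5]))[0] == pytest.approx(1.5)
        assert np.isnan(imap.map_times(np.array([1.5]))[0])  # removed stretch

    def test_round_trip_on_kept_samples(self, rng):
        rec = Recording(rng.standard_normal((1, 100)), fs=10.0, channel_labels=["a"])
        _, imap = apply_mask(rec, SegmentMask([(0.0, 3.0), (5.0, 8.5)]))
        kept = np.concatenate([np.arange(0, 30), np.arange(50, 85)])
        back = imap.new_to_orig_sample(imap.orig_to_new_sample(kept))
        np.testing.assert_array_equal(back, kept)

    def test_kept_plus_removed_is_total(self, rng):
        rec = Recording(rng.standard_normal((1, 1000)), fs=100.0, channel_labels=["a"])
        ev = EventTrain([1.0, 9.0])
        mask = inactive_segment_mask(ev, rec.span, 3.0)
        masked, _ = apply_mask(rec, mask)
        removed = rec.duration - mask.total_kept
        assert masked.duration + removed == pytest.approx(rec.duration, abs=1 / rec.fs)

    def test_empty_keep_set_errors(self, rng):
        rec = Recording(rng.standard_normal((1, 30)), fs=10.0, channel_labels=["a"])
        with pytest.raises(ValidationError):
            apply_mask(rec, SegmentMask([]))


@settings(derandomize=True, max_examples=25)
@given(st.lists(st.floats(0.1, 99.9), min_size=1, max_size=8, unique=True))
def test_mask_respects_bounds_property(event_list):
    mask = inactive_segment_mask(EventTrain(np.sort(event_list)), (0.0, 100.0), 10.0)
    for a, b in mask.keep_intervals:
        assert 0.0 <= a < b <= 100.0
    assert mask.total_kept <= 100.0
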