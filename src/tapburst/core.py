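"""Core containers and I/O: recordings, behavioral event trains, segment masks.

Conventions used throughout the package: times are seconds (float) at every API
boundary, sample indices are 0-based, and intervals are half-open ``[start,
end)``.  Sample ``i`` of a recording covers time ``t0 + i/fs``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


class ValidationError(ValueError):
    """Input violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in arbitrary units (µV-typical).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per signal row.
    channel_positions : ndarray or None
        Optional (n_channels, 2 or 3) coordinates, used for adjacency.
    t0 : float
        Recording start time in seconds (clock origin of the event train).
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_positions: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.signal.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("duplicate channel labels")
        bad = ~np.isfinite(self.signal)
        if bad.any():
            c, i = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite sample at channel {self.channel_labels[c]!r}, index {i}"
            )
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if self.channel_positions.shape[0] != self.signal.shape[0]:
                raise ValidationError("positions/channel count mismatch")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def span(self) -> tuple[float, float]:
        return (self.t0, self.t0 + self.duration)


@dataclass
class EventTrain:
    """Strictly increasing behavioral timestamps (seconds, recording clock)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValidationError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def restrict(self, start: float, end: float) -> "EventTrain":
        """Events within [start, end)."""
        keep = (self.times >= start) & (self.times < end)
        return EventTrain(self.times[keep])


@dataclass
class SegmentMask:
    """Kept [start, end) intervals in seconds; the complement is discarded."""

    keep_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = [(float(a), float(b)) for a, b in self.keep_intervals]
        for a, b in iv:
            if b <= a:
                raise ValidationError(f"empty or inverted interval ({a}, {b})")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValidationError("keep intervals overlap or are unsorted")
        self.keep_intervals = iv

    @property
    def total_kept(self) -> float:
        return sum(b - a for a, b in self.keep_intervals)

    def contains(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.keep_intervals)


@dataclass
class IndexMap:
    """Sample-index translation between original and masked clocks.

    ``orig_starts[k]`` is the first original sample of kept segment k,
    ``new_starts[k]`` its first masked sample, ``lengths[k]`` its length.
    ``seams`` are masked sample indices where a new segment begins (the first
    segment excluded): interval statistics must not straddle them.
    """

    orig_starts: np.ndarray
    new_starts: np.ndarray
    lengths: np.ndarray
    fs: float
    t0: float = 0.0

    @property
    def seams(self) -> np.ndarray:
        return self.new_starts[1:]

    @property
    def seam_times(self) -> np.ndarray:
        """Seam positions on the masked clock, in seconds."""
        return self.t0 + self.seams / self.fs

    def orig_to_new_sample(self, idx: np.ndarray) -> np.ndarray:
        """Map original sample indices to masked indices (-1 if removed)."""
        idx = np.asarray(idx)
        out = np.full(idx.shape, -1, dtype=int)
        for o, n, ln in zip(self.orig_starts, self.new_starts, self.lengths):
            sel = (idx >= o) & (idx < o + ln)
            out[sel] = idx[sel] - o + n
        return out

    def new_to_orig_sample(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        out = np.full(idx.shape, -1, dtype=int)
        for o, n, ln in zip(self.orig_starts, self.new_starts, self.lengths):
            sel = (idx >= n) & (idx < n + ln)
            out[sel] = idx[sel] - n + o
        return out

    def map_times(self, times: np.ndarray) -> np.ndarray:
        """Map original-clock times to masked-clock times (NaN if removed)."""
        times = np.asarray(times, dtype=float)
        idx = np.floor((times - self.t0) * self.fs).astype(int)
        new_idx = self.orig_to_new_sample(idx)
        frac = (times - self.t0) * self.fs - idx
        out = np.where(new_idx >= 0, self.t0 + (new_idx + frac) / self.fs, np.nan)
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NATIVE_HEADER_KEYS = {"fs", "labels"}


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording in the native format: ``<stem>.tsv`` numeric matrix
    (samples × channels, tab-delimited) plus ``<stem>.json`` header."""
    path = Path(path)
    stem = path.with_suffix("")
    header = {
        "fs": rec.fs,
        "labels": list(rec.channel_labels),
        "t0": rec.t0,
        "positions": None
        if rec.channel_positions is None
        else rec.channel_positions.tolist(),
    }
    stem.with_suffix(".json").write_text(json.dumps(header))
    np.savetxt(stem.with_suffix(".tsv"), rec.signal.T, delimiter="\t", fmt="%.10g")


def _read_native(path: Path) -> Recording:
    stem = path.with_suffix("")
    hdr_path = stem.with_suffix(".json")
    if not hdr_path.exists():
        raise FileNotFoundError(f"native header not found: {hdr_path}")
    header = json.loads(hdr_path.read_text())
    missing = _NATIVE_HEADER_KEYS - header.keys()
    if missing:
        raise ValidationError(f"native header missing keys: {sorted(missing)}")
    data = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    pos = header.get("positions")
    return Recording(
        signal=data.T,
        fs=float(header["fs"]),
        channel_labels=[str(x) for x in header["labels"]],
        channel_positions=None if pos is None else np.asarray(pos),
        t0=float(header.get("t0", 0.0)),
    )


def read_recording(path: str | Path, dialect: str = "native") -> Recording:
    """Read a continuous recording.

    ``dialect`` is one of ``native`` (text matrix + JSON header), ``edf`` or
    ``brainvision`` (delegated to MNE).  Sampling rate always comes from the
    file header; non-finite samples are rejected.
    """
    path = Path(path)
    if dialect == "native":
        return _read_native(path)
    if dialect in ("edf", "brainvision"):
        import mne

        reader = mne.io.read_raw_edf if dialect == "edf" else mne.io.read_raw_brainvision
        raw = reader(path, preload=True, verbose="error")
        pos = None
        montage = raw.get_montage()
        if montage is not None:
            ch_pos = montage.get_positions()["ch_pos"]
            if all(ch in ch_pos for ch in raw.ch_names):
                pos = np.array([ch_pos[ch] for ch in raw.ch_names])
        return Recording(
            signal=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            channel_positions=pos,
            t0=0.0,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def read_events(path: str | Path) -> tuple[EventTrain, int]:
    """Read a touch-event train from delimited text.

    One timestamp (seconds) per row, either a bare column or a ``time_s``
    column; an optional ``app_label`` column is carried through by I/O but
    ignored here.  Returns the sorted, deduplicated train and the number of
    duplicates dropped.
    """
    import re

    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return EventTrain(np.array([])), 0
    split = re.compile(r"[,\t;]| +").split
    col = 0
    if any(c.isalpha() for c in lines[0]):  # header row
        fields = [f.strip() for f in split(lines[0])]
        if "time_s" not in fields:
            raise ValidationError(f"no time_s column in {path}")
        col = fields.index("time_s")
        lines = lines[1:]
    vals = []
    for k, ln in enumerate(lines, start=1):
        token = [f.strip() for f in split(ln)][col]
        try:
            vals.append(float(token))
        except ValueError:
            raise ValidationError(
                f"non-numeric event time at data row {k} of {path}"
            ) from None
    arr = np.sort(np.asarray(vals))
    uniq = np.unique(arr)
    return EventTrain(uniq), int(arr.size - uniq.size)


def write_events(path: str | Path, events: EventTrain) -> None:
    pd.DataFrame({"time_s": events.times}).to_csv(path, index=False)


def write_segment_mask(path: str | Path, mask: SegmentMask) -> None:
    pd.DataFrame(mask.keep_intervals, columns=["start_s", "end_s"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# behavior-based inactive-segment filter
# ---------------------------------------------------------------------------


def inactive_segment_mask(
    events: EventTrain,
    recording_span: tuple[float, float],
    threshold_s: float = 30.0,
) -> SegmentMask:
    """Mark behaviorally inactive stretches for removal.

    A time point is removed iff its distance to the preceding event AND to the
    following event both exceed ``threshold_s``.  Recording edges carry no
    event (distance = ∞), so stretches more than ``threshold_s`` before the
    first or after the last event are removable.  Returns the complementary
    kept intervals.
    """
    if threshold_s <= 0:
        raise ValidationError("threshold_s must be positive")
    start, end = float(recording_span[0]), float(recording_span[1])
    t = events.times
    t = t[(t >= start) & (t <= end)]
    if t.size == 0:
        warnings.warn("no events in recording span: entire recording removed")
        return SegmentMask([])
    # around each event the window [t - thr, t + thr] is kept; the kept set is
    # the union of those windows clipped to the span
    kept: list[tuple[float, float]] = []
    for ti in t:
        a, b = max(start, ti - threshold_s), min(end, ti + threshold_s)
        if kept and a <= kept[-1][1]:
            kept[-1] = (kept[-1][0], max(kept[-1][1], b))
        else:
            kept.append((a, b))
    return SegmentMask(kept)


def apply_mask(rec: Recording, mask: SegmentMask) -> tuple[Recording, IndexMap]:
    """Concatenate kept segments; return the masked recording and an index map.

    Segment boundaries are snapped to samples (floor start, floor end,
    half-open).  The index map records concatenation seams so interval
    statistics never span one.
    """
    if not mask.keep_intervals:
        raise ValidationError("mask keeps nothing")
    lo, hi = rec.span
    pieces, orig_starts, lengths = [], [], []
    for a, b in mask.keep_intervals:
        if a < lo - 1e-9 or b > hi + 1e-9:
            raise ValidationError(f"mask interval ({a}, {b}) outside recording span")
        i0 = int(np.floor((a - rec.t0) * rec.fs))
        i1 = min(int(np.floor((b - rec.t0) * rec.fs)), rec.n_samples)
        if i1 <= i0:
            continue
        pieces.append(rec.signal[:, i0:i1])
        orig_starts.append(i0)
        lengths.append(i1 - i0)
    if not pieces:
        raise ValidationError("mask keeps nothing after snapping to samples")
    lengths = np.asarray(lengths)
    new_starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    masked = Recording(
        signal=np.concatenate(pieces, axis=1),
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        channel_positions=rec.channel_positions,
        t0=rec.t0,
    )
    imap = IndexMap(
        orig_starts=np.asarray(orig_starts),
        new_starts=new_starts,
        lengths=lengths,
        fs=rec.fs,
        t0=rec.t0,
    )
    return masked, imap


# ---------------------------------------------------------------------------
# simple zero-phase filters (optional preprocessing utilities)
# ---------------------------------------------------------------------------


def highpass(rec: Recording, cutoff_hz: float = 0.5, order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass (filtfilt)."""
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return Recording(out, rec.fs, rec.channel_labels, rec.channel_positions, rec.t0)


def bandpass(
    rec: Recording, lo_hz: float = 1.0, hi_hz: float = 45.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (filtfilt)."""
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return Recording(out, rec.fs, rec.channel_labels, rec.channel_positions, rec.t0)
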