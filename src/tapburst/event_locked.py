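"""Touch-locked burst dynamics: raster epoching, burst probability index (BPI),
suppression/rebound extrema, and touch↔burst latencies.

The BPI is the trial-averaged probability of being inside a burst as a
function of time relative to a behavioral event, baseline-corrected by
subtracting the median of the time course over the full epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EventTrain
from .detection import BurstSegment


@dataclass
class BurstRaster:
    """Trial × time binary raster per channel.

    ``data`` has shape (n_channels, n_trials, n_times); window endpoints are
    inclusive at both edges (±3 s at 1 kHz → 6001 samples).
    """

    data: np.ndarray
    window: tuple[float, float]
    fs: float
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        lo, hi = self.window
        n = self.data.shape[2]
        return lo + np.arange(n) / self.fs


@dataclass
class BPISeries:
    """Baseline-corrected burst probability per channel.

    ``raw`` in [0, 1]; ``bpi = raw − baseline`` with ``baseline`` the median of
    ``raw`` across epoch time points, per channel.
    """

    bpi: np.ndarray  # (n_channels, n_times)
    raw: np.ndarray
    baseline: np.ndarray  # (n_channels,)
    times: np.ndarray
    fs: float


@dataclass
class ExtremaResult:
    min_value: np.ndarray
    min_latency_s: np.ndarray
    max_value: np.ndarray
    max_latency_s: np.ndarray


def epoch_bursts(
    series: np.ndarray,
    events: EventTrain,
    fs: float,
    window: tuple[float, float] = (-3.0, 3.0),
    valid: np.ndarray | None = None,
    seam_samples: np.ndarray | None = None,
    t0: float = 0.0,
) -> BurstRaster:
    """Epoch the binary burst series from ``window[0]`` to ``window[1]`` s
    around each event (endpoints inclusive).

    Trials whose window leaves valid data, runs off the recording, or crosses
    a concatenation seam are dropped (counted in ``n_dropped``), never padded.
    """
    series = np.atleast_2d(np.asarray(series, dtype=bool))
    n_ch, n_t = series.shape
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be increasing")
    off_lo = int(round(lo * fs))
    off_hi = int(round(hi * fs))
    n_ep = off_hi - off_lo + 1
    if valid is None:
        valid = np.ones(n_t, dtype=bool)
    seam_samples = np.asarray(seam_samples if seam_samples is not None else [], dtype=int)

    rows, dropped = [], 0
    for t in events.times:
        c = int(round((t - t0) * fs))
        a, b = c + off_lo, c + off_hi
        if a < 0 or b >= n_t or not valid[a : b + 1].all():
            dropped += 1
            continue
        if seam_samples.size and np.any((seam_samples > a) & (seam_samples <= b)):
            dropped += 1
            continue
        rows.append(series[:, a : b + 1])
    if not rows:
        raise ValueError("no usable trials: every epoch fell outside valid data")
    data = np.stack(rows, axis=1)  # (n_ch, n_trials, n_ep)
    assert data.shape[2] == n_ep
    return BurstRaster(data=data, window=(lo, hi), fs=fs, n_dropped=dropped)


def compute_bpi(raster: BurstRaster) -> BPISeries:
    """Trial-average the raster and subtract the per-channel median over time."""
    raw = raster.data.mean(axis=1)
    baseline = np.median(raw, axis=1)
    return BPISeries(
        bpi=raw - baseline[:, np.newaxis],
        raw=raw,
        baseline=baseline,
        times=raster.times,
        fs=raster.fs,
    )


def bpi_extrema(
    bpi: BPISeries, search_window: tuple[float, float] = (-1.0, 1.0)
) -> ExtremaResult:
    """Minimum (suppression) and maximum (rebound) of the BPI in the search
    window, with their latencies.  Ties resolve to the first occurrence."""
    lo, hi = search_window
    sel = (bpi.times >= lo - 1e-12) & (bpi.times <= hi + 1e-12)
    if not sel.any():
        raise ValueError("search window outside epoch")
    t = bpi.times[sel]
    x = bpi.bpi[:, sel]
    imin = np.argmin(x, axis=1)
    imax = np.argmax(x, axis=1)
    return ExtremaResult(
        min_value=x[np.arange(x.shape[0]), imin],
        min_latency_s=t[imin],
        max_value=x[np.arange(x.shape[0]), imax],
        max_latency_s=t[imax],
    )


def touch_burst_latencies(
    segments: list[BurstSegment],
    events: EventTrain,
    channel_labels: list[str],
) -> dict[str, dict[str, np.ndarray]]:
    """Per touch, per channel: time to the next burst onset and time since the
    previous burst offset.

    A touch inside an ongoing burst skips that burst in both directions — the
    latencies refer to distinct neighboring bursts (within-burst touches are
    instead counted by the intra-burst touch rate).  Missing neighbors yield
    NaN.  Returns per-channel arrays plus their medians.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    by_ch: dict[str, list[BurstSegment]] = {lab: [] for lab in channel_labels}
    for s in segments:
        by_ch[s.channel].append(s)
    for lab in channel_labels:
        segs = sorted(by_ch[lab], key=lambda s: s.onset_s)
        onsets = np.array([s.onset_s for s in segs])
        offsets = np.array([s.offset_s for s in segs])
        to_onset = np.full(len(events), np.nan)
        from_offset = np.full(len(events), np.nan)
        for k, t in enumerate(events.times):
            if onsets.size == 0:
                continue
            inside = np.flatnonzero((onsets <= t) & (t < offsets))
            if inside.size:  # skip the ongoing burst in both directions
                j = inside[0]
                if j + 1 < onsets.size:
                    to_onset[k] = onsets[j + 1] - t
                if j - 1 >= 0:
                    from_offset[k] = t - offsets[j - 1]
            else:
                nxt = np.searchsorted(onsets, t, side="left")
                if nxt < onsets.size:
                    to_onset[k] = onsets[nxt] - t
                prev = np.searchsorted(offsets, t, side="right") - 1
                if prev >= 0:
                    from_offset[k] = t - offsets[prev]
        out[lab] = {
            "touch_to_onset_s": to_onset,
            "offset_to_touch_s": from_offset,
            "median_touch_to_onset_s": np.nanmedian(to_onset) if np.any(np.isfinite(to_onset)) else np.nan,
            "median_offset_to_touch_s": np.nanmedian(from_offset) if np.any(np.isfinite(from_offset)) else np.nan,
        }
    return out
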