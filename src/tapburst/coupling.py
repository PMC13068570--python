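"""Burst↔behavior coupling statistics.

Two per-channel scalars link the burst process to the touch stream:

* **Intra-burst touch rate (BTR)** — touches occurring while the burst series
  is ON, divided by the total burst duration (touches/second of burst time).
* **Burst-behavior timing index (BBTI)** — log10 difference between the median
  inter-touch interval that contains a burst and the median interval that does
  not.  Note the built-in sampling bias: longer intervals are more likely to
  contain a burst even when bursts are independent of behavior, so BBTI > 0
  is expected under independence and must be compared to a matched baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EventTrain


@dataclass
class CouplingResult:
    channel: str
    btr: float  # touches per second of burst time; NaN if no burst time
    bbti: float  # log10 median-interval difference; NaN if a group is empty
    n_with: int
    n_without: int


def intra_burst_touch_rate(
    series: np.ndarray,
    events: EventTrain,
    fs: float,
    valid: np.ndarray | None = None,
    t0: float = 0.0,
) -> np.ndarray:
    """BTR per channel: in-burst touches / total burst seconds.

    A touch is in-burst when the series is ON at the sample containing the
    touch (floor to sample index; half-open bursts, so a touch exactly on an
    offset sample counts as outside).  Channels with zero burst time get NaN.
    """
    series = np.atleast_2d(np.asarray(series, dtype=bool))
    n_ch, n_t = series.shape
    if valid is None:
        valid = np.ones(n_t, dtype=bool)
    idx = np.floor((events.times - t0) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_t)]
    idx = idx[valid[idx]]
    burst_s = series[:, valid].sum(axis=1) / fs
    out = np.full(n_ch, np.nan)
    for c in range(n_ch):
        if burst_s[c] > 0:
            out[c] = series[c, idx].sum() / burst_s[c]
    return out


def bbti(
    series: np.ndarray,
    events: EventTrain,
    fs: float,
    seam_times: np.ndarray | None = None,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BBTI per channel plus WITH/WITHOUT interval counts.

    Each consecutive inter-touch interval is WITH if any series sample whose
    time lies strictly inside the open interval (t_i, t_{i+1}) is ON, else
    WITHOUT.  Intervals crossing a concatenation seam are excluded.
    ``bbti = log10(median Δ | WITH) − log10(median Δ | WITHOUT)``; a channel
    whose groups are not both populated gets NaN with a warning.
    """
    series = np.atleast_2d(np.asarray(series, dtype=bool))
    n_ch, n_t = series.shape
    t = events.times
    if t.size < 2:
        raise ValueError("need at least 2 events")
    seam_times = np.asarray(seam_times if seam_times is not None else [], dtype=float)

    vals = np.full(n_ch, np.nan)
    n_with = np.zeros(n_ch, dtype=int)
    n_without = np.zeros(n_ch, dtype=int)
    deltas, has_burst = [], []
    for t_a, t_b in zip(t[:-1], t[1:]):
        if seam_times.size and np.any((seam_times > t_a) & (seam_times < t_b)):
            continue
        # samples at times j/fs strictly inside (t_a, t_b)
        j0 = int(np.floor((t_a - t0) * fs)) + 1
        j1 = int(np.ceil((t_b - t0) * fs))  # exclusive
        j0, j1 = max(j0, 0), min(j1, n_t)
        deltas.append(t_b - t_a)
        has_burst.append(series[:, j0:j1].any(axis=1) if j1 > j0 else np.zeros(n_ch, bool))
    if not deltas:
        return vals, n_with, n_without
    deltas = np.asarray(deltas)
    has_burst = np.stack(has_burst, axis=1)  # (n_ch, n_intervals)
    for c in range(n_ch):
        w = has_burst[c]
        n_with[c], n_without[c] = int(w.sum()), int((~w).sum())
        if n_with[c] and n_without[c]:
            vals[c] = np.log10(np.median(deltas[w])) - np.log10(np.median(deltas[~w]))
        else:
            warnings.warn(f"channel {c}: a BBTI group is empty; NaN returned")
    return vals, n_with, n_without


def coupling_table(
    channel_labels: list[str],
    btr_vals: np.ndarray,
    bbti_vals: np.ndarray,
    n_with: np.ndarray,
    n_without: np.ndarray,
) -> pd.DataFrame:
    from .metrics import znorm_channels

    def _z(x):
        x = np.asarray(x, float)
        if np.isnan(x).any() or x.size < 2:
            return np.full_like(x, np.nan)
        return znorm_channels(x)

    return pd.DataFrame(
        {
            "channel": channel_labels,
            "btr": btr_vals,
            "btr_z": _z(btr_vals),
            "bbti": bbti_vals,
            "bbti_z": _z(bbti_vals),
            "n_with": n_with,
            "n_without": n_without,
        }
    )
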