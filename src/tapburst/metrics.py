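"""Per-channel burst summary statistics: occupancy, counts, durations, z-maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import BurstMask, BurstSegment


@dataclass
class ChannelMetrics:
    channel: str
    bo: float
    n_bursts: int
    median_duration_s: float  # NaN when n_bursts == 0
    rate_hz: float


def burst_occupancy(mask: BurstMask, valid_duration_s: float | None = None) -> np.ndarray:
    """Burst occupancy per channel: total burst time / searched recording time.

    Equivalently the mean of the binary burst series over valid samples.  The
    denominator is the valid (edge-trimmed, post-mask) duration actually
    searched for bursts.
    """
    if valid_duration_s is None:
        valid_duration_s = mask.valid_duration
    if valid_duration_s <= 0:
        raise ValueError("valid duration must be positive")
    on_s = mask.series[:, mask.valid].sum(axis=1) / mask.fs
    return on_s / valid_duration_s


def channel_metrics(
    segments: list[BurstSegment],
    valid_duration_s: float,
    channel_labels: list[str],
) -> pd.DataFrame:
    """Count, median duration and rate per channel.

    Channels without bursts report ``median_duration_s`` = NaN.  Medians are
    per-channel over that channel's segments (per-electrode medians within a
    participant).
    """
    if valid_duration_s <= 0:
        raise ValueError("valid duration must be positive")
    by_ch: dict[str, list[float]] = {lab: [] for lab in channel_labels}
    bo: dict[str, float] = {lab: 0.0 for lab in channel_labels}
    for s in segments:
        by_ch[s.channel].append(s.duration_s)
        bo[s.channel] += s.duration_s
    rows = []
    for lab in channel_labels:
        durs = by_ch[lab]
        rows.append(
            {
                "channel": lab,
                "bo": bo[lab] / valid_duration_s,
                "n_bursts": len(durs),
                "median_duration_s": float(np.median(durs)) if durs else np.nan,
                "rate_hz": len(durs) / valid_duration_s,
            }
        )
    return pd.DataFrame(rows)


def znorm_channels(values: np.ndarray) -> np.ndarray:
    """z-normalize a per-channel scalar map across electrodes (sample sd, n−1).

    A constant map returns all zeros with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("z-normalization needs at least 2 channels")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("constant channel map: z-scores set to 0")
        return np.zeros_like(values)
    return (values - values.mean()) / sd
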