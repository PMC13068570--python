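"""Synthetic EEG sessions with ground-truth β-bursts and touch trains.

The generator emulates the statistical structure the analysis assumes:
per-channel 1/f^α Gaussian background, Hann-windowed sinusoidal burst atoms
(13–30 Hz, lognormal durations, Poisson occurrences), and a self-paced touch
stream with lognormal inter-touch intervals (median 0.871 s by default, the
typical smartphone inter-touch interval).  Burst-behavior coupling enters by
two separable mechanisms: a peri-touch gain g(τ) on the generative burst rate
(suppression before the touch, rebound after), and an optional thinning of
touches while a burst is ON (in-burst touch-hazard gain).

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning; identical seeds give identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import EventTrain, Recording

#: lognormal log-sd reproducing the ~1.24 s interquartile range of self-paced
#: touch streams when the median inter-touch interval is 0.871 s
DEFAULT_TOUCH_SIGMA = 0.977


@dataclass(frozen=True)
class Coupling:
    """Peri-touch modulation of the burst process and/or the touch hazard.

    ``suppression_gain``/``rebound_gain`` multiply the generative burst-onset
    rate inside their windows (seconds relative to the touch); windows may
    overlap across touches, with suppression taking precedence.
    ``touch_gain`` < 1 thins touch candidates that fall inside a burst.
    """

    suppression_gain: float = 0.3
    suppression_window: tuple[float, float] = (-0.8, 0.0)
    rebound_gain: float = 1.5
    rebound_window: tuple[float, float] = (0.2, 1.0)
    touch_gain: float = 1.0
    channels: tuple[int, ...] | None = None  # None = every channel rate-modulated


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of a synthetic session.

    Defaults give ~0.11 burst occupancy (rate × mean duration), in the range
    typically observed on the scalp, at the recording scale the analysis is
    designed for (continuous 1 kHz EEG).
    """

    n_channels: int = 8
    fs: float = 1000.0
    duration_s: float = 600.0
    background_exponent: float = 1.0  # 1/f^alpha
    background_rms: float = 1.0
    burst_rate_hz: float | tuple[float, ...] = 0.5
    burst_duration_median_s: float = 0.2
    burst_duration_sigma: float = 0.3
    burst_freq_range: tuple[float, float] = (13.0, 30.0)
    snr: float = 8.0  # atom peak power / background median power at atom freq
    touch_median_iti_s: float = 0.871
    touch_sigma: float = DEFAULT_TOUCH_SIGMA
    coupling: Coupling | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.burst_rate_hz, dtype=float))
        if np.any(rates < 0):
            raise ValueError("burst rates must be non-negative")
        if self.burst_duration_median_s <= 0 or self.touch_median_iti_s <= 0:
            raise ValueError("durations and intervals must be positive")

    def rates(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.burst_rate_hz, dtype=float))
        if r.size == 1:
            r = np.full(self.n_channels, r[0])
        if r.size != self.n_channels:
            raise ValueError("burst_rate_hz length must match n_channels")
        return r


@dataclass
class GroundTruth:
    """Injected-atom table, touch times, and the true per-channel ON series."""

    atoms: pd.DataFrame  # channel, onset_s, duration_s, freq_hz, amplitude, truncated
    event_times: np.ndarray
    series: np.ndarray  # (n_channels, n_samples) bool, ON inside an atom
    fs: float

    @property
    def occupancy(self) -> np.ndarray:
        return self.series.mean(axis=1)


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def gen_background(cfg: SynthConfig, rng: np.random.Generator) -> Recording:
    """Independent per-channel 1/f^α Gaussian noise, RMS-normalized."""
    n = int(round(cfg.duration_s * cfg.fs))
    freqs = np.fft.rfftfreq(n, d=1 / cfg.fs)
    shape = np.ones_like(freqs)
    if cfg.background_exponent != 0:
        shape[1:] = freqs[1:] ** (-cfg.background_exponent / 2.0)
        shape[0] = 0.0
    sig = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white) * shape
        x = np.fft.irfft(spec, n=n)
        rms = np.sqrt(np.mean(x**2))
        sig[c] = cfg.background_rms * x / rms
    labels = [f"ch{c:02d}" for c in range(cfg.n_channels)]
    theta = 2 * np.pi * np.arange(cfg.n_channels) / cfg.n_channels
    pos = np.column_stack([np.cos(theta), np.sin(theta)])
    return Recording(sig, cfg.fs, labels, channel_positions=pos)


# ---------------------------------------------------------------------------
# burst-atom timing
# ---------------------------------------------------------------------------


def _rate_gain(
    cfg: SynthConfig, touch_times: np.ndarray | None, n: int
) -> np.ndarray | None:
    """Peri-touch gain g(τ) evaluated on the sample grid (None if flat)."""
    cp = cfg.coupling
    if cp is None or touch_times is None or touch_times.size == 0:
        return None
    g = np.ones(n)
    fs = cfg.fs

    def _paint(window: tuple[float, float], value: float) -> None:
        for t in touch_times:
            a = max(int(np.floor((t + window[0]) * fs)), 0)
            b = min(int(np.ceil((t + window[1]) * fs)), n)
            if b > a:
                g[a:b] = value

    _paint(cp.rebound_window, cp.rebound_gain)
    _paint(cp.suppression_window, cp.suppression_gain)  # suppression wins overlaps
    return g


def draw_atom_times(
    rate_hz: float,
    duration_s: float,
    rng: np.random.Generator,
    gain: np.ndarray | None = None,
    fs: float = 1000.0,
) -> np.ndarray:
    """Poisson atom occurrence times (atom centers), optionally
    rate-modulated by a gain series (inhomogeneous Poisson via thinning).

    The gain is evaluated at the atom *center*: a burst is one event, and
    tying the modulation to its midpoint keeps the suppression of the
    resulting ON series symmetric around the gain window instead of smearing
    it one atom-duration forward.
    """
    if rate_hz <= 0:
        return np.array([])
    if gain is None:
        n = rng.poisson(rate_hz * duration_s)
        return np.sort(rng.uniform(0, duration_s, n))
    gmax = float(gain.max())
    if gmax <= 0:
        return np.array([])
    n = rng.poisson(rate_hz * gmax * duration_s)
    cand = np.sort(rng.uniform(0, duration_s, n))
    idx = np.minimum((cand * fs).astype(int), gain.size - 1)
    keep = rng.uniform(0, gmax, n) < gain[idx]
    return cand[keep]


def gen_burst_series(
    cfg: SynthConfig,
    rng: np.random.Generator,
    touch_times: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ground-truth burst intervals and binary ON series, without waveforms.

    Used on its own when only burst *timing* matters (event-locked and
    coupling simulations); ``inject_bursts`` adds the waveforms on top.
    """
    n = int(round(cfg.duration_s * cfg.fs))
    rates = cfg.rates()
    gain = _rate_gain(cfg, touch_times, n)
    coupled = set(
        range(cfg.n_channels)
        if (cfg.coupling and cfg.coupling.channels is None)
        else (cfg.coupling.channels if cfg.coupling else ())
    )
    mu = np.log(cfg.burst_duration_median_s)
    f_lo, f_hi = cfg.burst_freq_range
    series = np.zeros((cfg.n_channels, n), dtype=bool)
    rows = []
    for c in range(cfg.n_channels):
        centers = draw_atom_times(
            rates[c], cfg.duration_s, rng, gain if c in coupled else None, cfg.fs
        )
        durs = np.exp(mu + cfg.burst_duration_sigma * rng.standard_normal(centers.size))
        freqs = rng.uniform(f_lo, f_hi, centers.size)
        for ctr, d, f in zip(centers, durs, freqs):
            o = ctr - d / 2.0
            truncated = o < 0 or o + d > cfg.duration_s
            o_eff = max(o, 0.0)
            d_eff = min(o + d, cfg.duration_s) - o_eff
            if d_eff <= 0:
                continue
            i0, i1 = int(round(o_eff * cfg.fs)), int(round((o_eff + d_eff) * cfg.fs))
            series[c, i0:i1] = True
            rows.append(
                {
                    "channel": c,
                    "onset_s": o_eff,
                    "duration_s": d_eff,
                    "freq_hz": f,
                    "amplitude": np.nan,
                    "truncated": truncated,
                }
            )
    atoms = pd.DataFrame(
        rows, columns=["channel", "onset_s", "duration_s", "freq_hz", "amplitude", "truncated"]
    )
    return series, atoms


# ---------------------------------------------------------------------------
# waveform synthesis and SNR calibration
# ---------------------------------------------------------------------------

_unit_peak_cache: dict[tuple[float, int], float] = {}


def _unit_atom_peak_power(freq_bin: float, dur_ms: int, fs: float, n_cycles: float = 7.0) -> float:
    """Peak Morlet power (at ``freq_bin``) of a unit-amplitude Hann atom.

    Memoized on (frequency bin, duration rounded to 10 ms); provides the
    amplitude calibration that turns the configured SNR into volts.
    """
    key = (freq_bin, dur_ms)
    if key in _unit_peak_cache:
        return _unit_peak_cache[key]
    from mne.time_frequency import tfr_array_morlet

    pad = 2.0  # seconds either side; > widest wavelet half-length
    nd = max(int(round(dur_ms / 1000 * fs)), 2)
    t = np.arange(nd) / fs
    atom = np.hanning(nd) * np.sin(2 * np.pi * freq_bin * t)
    buf = np.zeros(int(2 * pad * fs) + nd)
    buf[int(pad * fs) : int(pad * fs) + nd] = atom
    p = tfr_array_morlet(
        buf[np.newaxis, np.newaxis],
        sfreq=fs,
        freqs=[freq_bin],
        n_cycles=n_cycles,
        output="power",
        zero_mean=False,
    )[0, 0, 0]
    _unit_peak_cache[key] = float(p.max())
    return _unit_peak_cache[key]


def _background_median_power(
    rec: Recording, freqs: np.ndarray, n_cycles: float = 7.0, max_seconds: float = 60.0
) -> np.ndarray:
    """Median Morlet power per frequency of the (pre-injection) background,
    estimated from an initial slice and averaged over channels."""
    from mne.time_frequency import tfr_array_morlet

    n = min(int(max_seconds * rec.fs), rec.n_samples)
    out = np.empty((rec.n_channels, freqs.size))
    for c in range(rec.n_channels):
        p = tfr_array_morlet(
            rec.signal[c, :n][np.newaxis, np.newaxis],
            sfreq=rec.fs,
            freqs=freqs,
            n_cycles=n_cycles,
            output="power",
            zero_mean=False,
        )[0, 0]
        edge = int(np.ceil(5 * n_cycles / (2 * np.pi * freqs[0]) * rec.fs))
        out[c] = np.median(p[:, edge : n - edge], axis=1)
    return out.mean(axis=0)


def inject_bursts(
    rec: Recording,
    cfg: SynthConfig,
    rng: np.random.Generator,
    touch_times: np.ndarray | None = None,
    freq_grid: np.ndarray | None = None,
) -> tuple[Recording, GroundTruth]:
    """Add Hann-windowed sinusoidal burst atoms to a background recording.

    Atom amplitudes are set so the peak wavelet power at the atom's nearest
    analysis frequency equals ``cfg.snr`` × the background median power there.
    Atoms extending past the recording end are truncated and flagged.
    """
    if freq_grid is None:
        freq_grid = np.arange(cfg.burst_freq_range[0], cfg.burst_freq_range[1] + 1e-9)
    series, atoms = gen_burst_series(cfg, rng, touch_times)
    sig = rec.signal.copy()
    n = sig.shape[1]
    if len(atoms):
        med_bg = _background_median_power(rec, freq_grid)
        amps = np.empty(len(atoms))
        for k, row in enumerate(atoms.itertuples(index=False)):
            bin_i = int(np.argmin(np.abs(freq_grid - row.freq_hz)))
            f_bin = float(freq_grid[bin_i])
            dur_ms = int(round(row.duration_s * 100)) * 10  # 10 ms resolution
            p_unit = _unit_atom_peak_power(f_bin, max(dur_ms, 10), rec.fs)
            amp = np.sqrt(cfg.snr * med_bg[bin_i] / p_unit)
            amps[k] = amp
            nd = max(int(round(row.duration_s * rec.fs)), 2)
            i0 = int(round(row.onset_s * rec.fs))
            i1 = min(i0 + nd, n)
            t = np.arange(i1 - i0) / rec.fs
            phase = rng.uniform(0, 2 * np.pi)
            sig[int(row.channel), i0:i1] += (
                amp * np.hanning(nd)[: i1 - i0] * np.sin(2 * np.pi * row.freq_hz * t + phase)
            )
        atoms = atoms.assign(amplitude=amps)
    out = Recording(sig, rec.fs, rec.channel_labels, rec.channel_positions, rec.t0)
    gt = GroundTruth(
        atoms=atoms,
        event_times=touch_times if touch_times is not None else np.array([]),
        series=series,
        fs=rec.fs,
    )
    return out, gt


# ---------------------------------------------------------------------------
# touch trains
# ---------------------------------------------------------------------------


def gen_touch_train(
    cfg: SynthConfig,
    rng: np.random.Generator,
    burst_series: np.ndarray | None = None,
) -> EventTrain:
    """Renewal touch stream with lognormal inter-touch intervals.

    When ``cfg.coupling.touch_gain`` < 1 and a ground-truth burst ON/OFF
    series is supplied, candidates falling inside a burst are thinned with
    probability 1 − touch_gain (``burst_series`` may be 1-D, or 2-D in which
    case any-channel ON counts).
    """
    mu = np.log(cfg.touch_median_iti_s)
    g_touch = cfg.coupling.touch_gain if cfg.coupling else 1.0
    on = None
    if burst_series is not None and g_touch < 1.0:
        on = np.atleast_2d(burst_series).any(axis=0)
    times = []
    t = float(np.exp(mu + cfg.touch_sigma * rng.standard_normal()))
    while t < cfg.duration_s:
        keep = True
        if on is not None:
            i = int(t * cfg.fs)
            if i < on.size and on[i]:
                keep = rng.uniform() < g_touch
        if keep:
            times.append(t)
        t += float(np.exp(mu + cfg.touch_sigma * rng.standard_normal()))
    return EventTrain(np.asarray(times))


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------


def gen_session(
    cfg: SynthConfig, with_waveforms: bool = True
) -> tuple[Recording | None, EventTrain, GroundTruth]:
    """One synthetic session from ``cfg.seed``.

    Order: touch candidates are drawn first (unthinned); bursts follow, with
    the peri-touch rate gain if coupling is configured; finally touch thinning
    (if any) is applied against the ground-truth burst series.  With
    ``with_waveforms=False`` the Recording is None and only the ground-truth
    series is produced (fast path for timing-only simulations).
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_bg, r_touch, r_burst, r_thin = [np.random.default_rng(s) for s in ss.spawn(4)]

    touches = gen_touch_train(cfg, r_touch)  # unthinned candidates
    if with_waveforms:
        bg = gen_background(cfg, r_bg)
        rec, gt = inject_bursts(bg, cfg, r_burst, touch_times=touches.times)
    else:
        rec = None
        series, atoms = gen_burst_series(cfg, r_burst, touch_times=touches.times)
        gt = GroundTruth(atoms=atoms, event_times=touches.times, series=series, fs=cfg.fs)

    g_touch = cfg.coupling.touch_gain if cfg.coupling else 1.0
    if g_touch < 1.0:
        on = gt.series.any(axis=0)
        idx = np.minimum((touches.times * cfg.fs).astype(int), on.size - 1)
        keep = ~on[idx] | (r_thin.uniform(size=len(touches)) < g_touch)
        touches = EventTrain(touches.times[keep])
    gt.event_times = touches.times
    return rec, touches, gt


def gen_dataset(
    cfg: SynthConfig,
    n_participants: int,
    jitter_sd: float = 0.0,
    with_waveforms: bool = True,
) -> list[tuple[Recording | None, EventTrain, GroundTruth]]:
    """Independent participants with deterministic per-participant seeds.

    ``jitter_sd`` applies multiplicative lognormal jitter to each
    participant's burst and touch rates (0 = identical configs).
    """
    master = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n_participants)]
    jit_rng = np.random.default_rng(master.spawn(1)[0])
    out = []
    for p in range(n_participants):
        pc = replace(cfg, seed=seeds[p])
        if jitter_sd > 0:
            jb, jt = np.exp(jitter_sd * jit_rng.standard_normal(2))
            rates = tuple(cfg.rates() * jb)
            pc = replace(pc, burst_rate_hz=rates, touch_median_iti_s=cfg.touch_median_iti_s / jt)
        out.append(gen_session(pc, with_waveforms=with_waveforms))
    return out
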