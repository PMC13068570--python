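"""End-to-end validation experiments on synthetic ground truth.

Each function here runs one self-contained study-condition experiment —
detector/oracle agreement, atom recovery, null calibrations, coupling
recovery, bootstrap type-I error — and returns plain numbers.  The test suite
asserts on them; ``scripts/acceptance.py`` reports them.

The per-sample reference detector in :func:`brute_force_detect` is written as
literal loops over the two detection rules and is kept independent of the
vectorized implementation in :mod:`tapburst.detection`.
"""

from __future__ import annotations

import filecmp
from dataclasses import replace
from pathlib import Path

import numpy as np

from .core import EventTrain
from .coupling import bbti, intra_burst_touch_rate
from .detection import BurstMask, DetectionParams, TFPower, detect_bursts, extract_segments, tf_decompose
from .event_locked import bpi_extrema, compute_bpi, epoch_bursts
from .group_stats import cluster_bootstrap, ring_adjacency
from .metrics import burst_occupancy
from .synth import Coupling, SynthConfig, gen_session

# ---------------------------------------------------------------------------
# 1. detector vs literal per-sample reference
# ---------------------------------------------------------------------------


def brute_force_detect(
    power: np.ndarray,
    freqs: np.ndarray,
    fs: float,
    valid: np.ndarray,
    threshold_factor: float = 6.0,
    min_cycles: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Literal per-sample implementation of the two burst rules.

    Power must strictly exceed ``threshold_factor`` × the median of the valid
    samples of that channel-frequency trace, and the suprathreshold run must
    last at least ``min_cycles / freq`` seconds.
    """
    n_ch, n_f, n_t = power.shape
    tf_mask = np.zeros((n_ch, n_f, n_t), dtype=bool)
    for c in range(n_ch):
        for i in range(n_f):
            vals = [power[c, i, t] for t in range(n_t) if valid[i, t]]
            if not vals:
                continue
            thr = threshold_factor * np.median(vals)
            supra = [bool(valid[i, t] and power[c, i, t] > thr) for t in range(n_t)]
            t = 0
            while t < n_t:
                if supra[t]:
                    u = t
                    while u < n_t and supra[u]:
                        u += 1
                    if (u - t) >= min_cycles * fs / freqs[i]:
                        tf_mask[c, i, t:u] = True
                    t = u
                else:
                    t += 1
    series = tf_mask.any(axis=1)
    return tf_mask, series


def detector_oracle_check(seed: int = 0, n_matrices: int = 100) -> dict:
    """Compare ``detect_bursts`` with the reference on random small TF matrices."""
    rng = np.random.default_rng(seed)
    n_agree = 0
    for _ in range(n_matrices):
        n_ch = rng.integers(1, 4)
        n_f = rng.integers(1, 6)
        n_t = rng.integers(50, 2001)
        fs = float(rng.choice([250.0, 500.0, 1000.0]))
        freqs = np.sort(rng.uniform(13, 30, n_f))
        freqs += np.arange(n_f) * 1e-6  # keep strictly increasing
        # heavy-tailed power with occasional plateaus/ties at the threshold
        power = rng.exponential(1.0, (n_ch, n_f, n_t))
        power[rng.uniform(size=power.shape) < 0.05] *= 20
        valid = rng.uniform(size=(n_f, n_t)) > 0.05
        tf = TFPower(power=power, freqs=freqs, fs=fs, valid=valid)
        params = DetectionParams(
            f_lo=float(freqs[0]), f_hi=float(freqs[-1]) + 1e-6, threshold_factor=6.0, min_cycles=2.0
        )
        got = detect_bursts(tf, params)
        ref_tf, ref_series = brute_force_detect(power, freqs, fs, valid)
        if np.array_equal(got.tf_mask, ref_tf) and np.array_equal(got.series, ref_series):
            n_agree += 1
    return {"n_agree": n_agree, "n_total": n_matrices}


# ---------------------------------------------------------------------------
# 2. atom recovery through the full detector
# ---------------------------------------------------------------------------


def _overlap_match(
    segs, atoms, channel_labels, fs: float
) -> tuple[float, float]:
    """Recall: atoms with >= 50% of their extent covered by detections on
    their channel.  Precision: detections with >= 50% of their extent covered
    by atoms."""
    seg_iv: dict[int, list[tuple[float, float]]] = {}
    for s in segs:
        seg_iv.setdefault(channel_labels.index(s.channel), []).append((s.onset_s, s.offset_s))
    atom_iv: dict[int, list[tuple[float, float]]] = {}
    for row in atoms.itertuples(index=False):
        atom_iv.setdefault(int(row.channel), []).append(
            (row.onset_s, row.onset_s + row.duration_s)
        )

    def _covered(iv: tuple[float, float], others: list[tuple[float, float]]) -> float:
        a0, a1 = iv
        # others are non-overlapping for segments; atoms may overlap, so merge
        merged: list[list[float]] = []
        for b0, b1 in sorted(others):
            if merged and b0 <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b1)
            else:
                merged.append([b0, b1])
        return sum(max(0.0, min(a1, b1) - max(a0, b0)) for b0, b1 in merged)

    n_atoms = n_hit = 0
    for c, ivs in atom_iv.items():
        for iv in ivs:
            n_atoms += 1
            if _covered(iv, seg_iv.get(c, [])) >= 0.5 * (iv[1] - iv[0]):
                n_hit += 1
    n_segs = n_tp = 0
    for c, ivs in seg_iv.items():
        for iv in ivs:
            n_segs += 1
            if _covered(iv, atom_iv.get(c, [])) >= 0.5 * (iv[1] - iv[0]):
                n_tp += 1
    recall = n_hit / n_atoms if n_atoms else np.nan
    precision = n_tp / n_segs if n_segs else np.nan
    return recall, precision


def burst_recovery(
    seed: int = 0,
    n_channels: int = 8,
    duration_s: float = 600.0,
    snr: float = 8.0,
    duration_median_s: float = 0.2,
) -> dict:
    """Full-detector recall/precision against injected ground-truth atoms."""
    cfg = SynthConfig(
        n_channels=n_channels,
        duration_s=duration_s,
        snr=snr,
        burst_duration_median_s=duration_median_s,
        seed=seed,
    )
    rec, _, gt = gen_session(cfg)
    tf = tf_decompose(rec)
    mask = detect_bursts(tf)
    segs = extract_segments(mask, tf, rec.channel_labels)
    recall, precision = _overlap_match(segs, gt.atoms, rec.channel_labels, rec.fs)
    bo = burst_occupancy(mask)
    return {
        "recall": recall,
        "precision": precision,
        "n_atoms": len(gt.atoms),
        "n_detected": len(segs),
        "mean_bo": float(bo.mean()),
        "_mask": mask,
        "_segs": segs,
        "_labels": rec.channel_labels,
    }


def occupancy_consistency(mask: BurstMask, segs, channel_labels) -> float:
    """Max |BO via segments − BO via series mean| across channels (should be
    below one sample's worth, 1/valid_samples)."""
    valid_s = mask.valid_duration
    bo_series = burst_occupancy(mask)
    seg_sum = np.zeros(mask.n_channels)
    for s in segs:
        c = channel_labels.index(s.channel)
        # restrict to valid samples, as the series route does
        i0, i1 = int(round(s.onset_s * mask.fs)), int(round(s.offset_s * mask.fs))
        seg_sum[c] += mask.valid[i0:i1].sum() / mask.fs
    bo_segs = seg_sum / valid_s
    return float(np.max(np.abs(bo_segs - bo_series)))


# ---------------------------------------------------------------------------
# 4. BPI null calibration against the analytic binomial band
# ---------------------------------------------------------------------------


def bpi_null_calibration(
    seed: int = 0, n_sims: int = 50, fixed_time_s: float = 0.5, z: float = 2.576
) -> dict:
    """With bursts independent of touches, the raw BPI at a fixed peri-event
    time should stay inside the 99% binomial band p ± z·sqrt(p(1−p)/n) for all
    but ~1% of channels.  Returns the exceedance fraction over all sims."""
    ss = np.random.SeedSequence([seed, 4])
    n_exceed = n_channels_total = 0
    for child in ss.spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        cfg = SynthConfig(seed=s)
        _, events, gt = gen_session(cfg, with_waveforms=False)
        raster = epoch_bursts(gt.series, events, cfg.fs)
        bpi = compute_bpi(raster)
        i = int(np.argmin(np.abs(bpi.times - fixed_time_s)))
        p = gt.series.mean(axis=1)
        half = z * np.sqrt(p * (1 - p) / raster.n_trials)
        n_exceed += int(np.sum(np.abs(bpi.raw[:, i] - p) > half))
        n_channels_total += cfg.n_channels
    return {
        "exceed_fraction": n_exceed / n_channels_total,
        "n_channels_total": n_channels_total,
    }


# ---------------------------------------------------------------------------
# 5. suppression/rebound recovery by bpi_extrema
# ---------------------------------------------------------------------------


def coupling_recovery(
    seed: int = 0, n_seeds: int = 20, duration_s: float = 1800.0
) -> dict:
    """Peri-touch rate gain (0.3× in [−0.8, 0] s, 1.5× in [0.2, 1] s) on half
    the channels; recovery = negative min latency AND positive max latency.
    Returns per-group recovery rates across seeds.

    Sessions are longer than the generator default because the recoverable
    rebound bump is small: neighboring touches overlap the ±1 s analysis
    window at the default touch cadence (the next touch's suppression eats
    into the own rebound, the previous touch's rebound elevates the left
    edge), leaving ~+0.02 of baseline-corrected probability to detect.
    ~1300 trials per session puts the Monte-Carlo error of the BPI
    (~sqrt(p/n)) at ~0.009, well under that bump.
    """
    coupled = (0, 1, 2, 3)
    cfg0 = SynthConfig(duration_s=duration_s, coupling=Coupling(channels=coupled))
    ss = np.random.SeedSequence([seed, 5])
    n_ch = cfg0.n_channels
    success = np.zeros((n_seeds, n_ch), dtype=bool)
    for k, child in enumerate(ss.spawn(n_seeds)):
        s = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(cfg0, seed=s)
        _, events, gt = gen_session(cfg, with_waveforms=False)
        raster = epoch_bursts(gt.series, events, cfg.fs)
        ext = bpi_extrema(compute_bpi(raster))
        success[k] = (ext.min_latency_s < 0) & (ext.max_latency_s > 0)
    rates = success.mean(axis=0)
    uncoupled = [c for c in range(n_ch) if c not in coupled]
    return {
        "coupled_rate": float(rates[list(coupled)].mean()),
        "uncoupled_rate": float(rates[uncoupled].mean()),
        "coupled_min_rate": float(rates[list(coupled)].min()),
        "uncoupled_max_rate": float(rates[uncoupled].max()),
        "per_channel_rates": rates,
    }


# ---------------------------------------------------------------------------
# 6 & 7. BTR/BBTI directionality and the sampling-bias property
# ---------------------------------------------------------------------------

#: burst rate giving ~0.12 occupancy at the default duration distribution
_RATE_FOR_OCC_012 = 0.12 / (0.2 * np.exp(0.3**2 / 2))


def _session_coupling_stats(cfg: SynthConfig) -> tuple[float, float, float]:
    """(mean btr, overall touch rate, mean bbti) of one fast session."""
    _, events, gt = gen_session(cfg, with_waveforms=False)
    btr_vals = intra_burst_touch_rate(gt.series, events, cfg.fs)
    bb, _, _ = bbti(gt.series, events, cfg.fs)
    overall = len(events) / cfg.duration_s
    return float(np.nanmean(btr_vals)), overall, float(np.nanmean(bb))


def btr_bbti_directionality(seed: int = 0, n_reps: int = 50, g_touch: float = 0.5) -> dict:
    """Touch thinning during bursts (hazard × g_touch) must pull BTR below the
    overall touch rate and push BBTI above the independent-process baseline at
    matched occupancy."""
    ss = np.random.SeedSequence([seed, 6])
    n_btr_below = 0
    bbti_coupled, bbti_indep = [], []
    for child in ss.spawn(n_reps):
        s = int(child.generate_state(1)[0] % (2**31))
        base = dict(burst_rate_hz=_RATE_FOR_OCC_012, seed=s)
        cfg_c = SynthConfig(
            coupling=Coupling(suppression_gain=1.0, rebound_gain=1.0, touch_gain=g_touch),
            **base,
        )
        btr_c, overall_c, bb_c = _session_coupling_stats(cfg_c)
        cfg_i = SynthConfig(**base)
        _, _, bb_i = _session_coupling_stats(cfg_i)
        n_btr_below += int(btr_c < overall_c)
        bbti_coupled.append(bb_c)
        bbti_indep.append(bb_i)
    return {
        "n_btr_below": n_btr_below,
        "n_reps": n_reps,
        "mean_bbti_coupled": float(np.nanmean(bbti_coupled)),
        "mean_bbti_independent": float(np.nanmean(bbti_indep)),
    }


def bbti_sampling_bias(seed: int = 0, n_sims: int = 100) -> dict:
    """Independent stationary bursts still yield mean BBTI > 0: longer
    inter-touch intervals are more likely to contain a burst."""
    ss = np.random.SeedSequence([seed, 7])
    vals = []
    for child in ss.spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        cfg = SynthConfig(n_channels=4, duration_s=300.0, seed=s)
        _, events, gt = gen_session(cfg, with_waveforms=False)
        bb, _, _ = bbti(gt.series, events, cfg.fs)
        vals.append(np.nanmean(bb))
    return {"mean_bbti": float(np.nanmean(vals)), "n_sims": n_sims}


# ---------------------------------------------------------------------------
# 8. cluster-bootstrap type-I error
# ---------------------------------------------------------------------------


def cluster_fwer(
    seed: int = 0,
    n_datasets: int = 200,
    n_participants: int = 20,
    n_channels: int = 16,
    n_time: int = 200,
    n_boot: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Family-wise error rate of the cluster bootstrap on pure-noise groups."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    adj = ring_adjacency(n_channels)
    n_false = 0
    for _ in range(n_datasets):
        data = rng.standard_normal((n_participants, n_channels, n_time))
        sm = cluster_bootstrap(data, adj, alpha=alpha, n_boot=n_boot, seed=rng)
        n_false += int(sm.significant.any())
    fwer = n_false / n_datasets
    se = np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {"fwer": fwer, "alpha": alpha, "binomial_se": float(se), "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# 10. pipeline determinism
# ---------------------------------------------------------------------------


def determinism_check(tmp_dir: str | Path, seed: int = 0) -> dict:
    """Run the full synthetic pipeline twice with one seed; compare bytes."""
    from .pipeline import PipelineConfig, run_single

    tmp_dir = Path(tmp_dir)
    outs = []
    for tag in ("a", "b"):
        cfg = PipelineConfig(
            synth=SynthConfig(n_channels=3, duration_s=300.0, seed=seed),
            out_dir=str(tmp_dir / tag),
            seed=seed,
        )
        run_single(cfg)
        outs.append(tmp_dir / tag)
    names = sorted(p.name for p in outs[0].iterdir())
    identical = all(
        filecmp.cmp(outs[0] / n, outs[1] / n, shallow=False)
        for n in names
        if n != "manifest.json"  # manifest embeds wall-clock timings
    )
    tables_a = [n for n in names if n.endswith(".csv")]
    return {"identical": bool(identical), "n_tables": len(tables_a)}
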