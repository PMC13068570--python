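"""End-to-end orchestration: single-session analysis and group-level pooling.

``run_single`` takes one recording + event train (real files or a synthetic
session) through detection, occupancy metrics, touch-locked BPI, extrema and
coupling, writing every table plus a JSON run manifest.  ``run_group`` pools
per-participant outputs and applies the population statistics: Bonferroni-
corrected one-sample t-tests for scalar channel maps, spatio-temporal cluster
bootstrap for the BPI channel×time image.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    EventTrain,
    Recording,
    apply_mask,
    inactive_segment_mask,
    read_events,
    read_recording,
)
from .coupling import bbti, coupling_table, intra_burst_touch_rate
from .detection import DetectionParams, detect_bursts, extract_segments, segments_to_frame, tf_decompose
from .event_locked import bpi_extrema, compute_bpi, epoch_bursts
from .group_stats import adjacency_from_positions, bonferroni_map, cluster_bootstrap
from .metrics import burst_occupancy, channel_metrics, znorm_channels
from .synth import Coupling, SynthConfig, gen_session

log = logging.getLogger("tapburst")


@dataclass
class PipelineConfig:
    """Validated run configuration (exactly one of input paths / synth)."""

    recording_path: str | None = None
    events_path: str | None = None
    recording_dialect: str = "native"
    synth: SynthConfig | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    epoch_window: tuple[float, float] = (-3.0, 3.0)
    extrema_window: tuple[float, float] = (-1.0, 1.0)
    inactivity_threshold_s: float = 30.0
    apply_inactivity_filter: bool = False
    alpha: float = 0.05
    n_boot: int = 1000
    out_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.recording_path is not None or self.events_path is not None
        if has_files and self.synth is not None:
            raise ValueError("config must set input paths OR a synth section, not both")
        if not has_files and self.synth is None:
            raise ValueError("config must set input paths or a synth section")
        if has_files and (self.recording_path is None or self.events_path is None):
            raise ValueError("both recording_path and events_path are required")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synth" in raw and raw["synth"] is not None:
        s = raw["synth"]
        if "coupling" in s and s["coupling"] is not None:
            s["coupling"] = Coupling(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in s["coupling"].items()})
        for k in ("burst_freq_range",):
            if k in s and isinstance(s[k], list):
                s[k] = tuple(s[k])
        raw["synth"] = SynthConfig(**s)
    if "detection" in raw and raw["detection"] is not None:
        raw["detection"] = DetectionParams(**raw["detection"])
    for k in ("epoch_window", "extrema_window"):
        if k in raw and isinstance(raw[k], list):
            raw[k] = tuple(raw[k])
    return PipelineConfig(**raw)


def _load_inputs(cfg: PipelineConfig) -> tuple[Recording, EventTrain]:
    if cfg.synth is not None:
        from dataclasses import replace

        rec, events, _ = gen_session(replace(cfg.synth, seed=cfg.seed))
        return rec, events
    rec = read_recording(cfg.recording_path, cfg.recording_dialect)
    events, n_dup = read_events(cfg.events_path)
    if n_dup:
        log.info("dropped %d duplicate events", n_dup)
    return rec, events


def run_single(cfg: PipelineConfig) -> dict:
    """Analyze one session; returns the result bundle and writes all tables."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, events = _load_inputs(cfg)
    labels = rec.channel_labels
    stage_log: list[dict] = []

    seam_samples = np.array([], dtype=int)
    if cfg.apply_inactivity_filter:
        mask = inactive_segment_mask(events, rec.span, cfg.inactivity_threshold_s)
        rec, imap = apply_mask(rec, mask)
        seam_samples = imap.seams
        mapped = imap.map_times(events.times)
        events = EventTrain(mapped[np.isfinite(mapped)])
        stage_log.append({"stage": "inactivity_filter", "kept_s": mask.total_kept})

    t0 = time.time()
    tf = tf_decompose(rec, cfg.detection)
    mask_b = detect_bursts(tf, cfg.detection)
    segs = extract_segments(mask_b, tf, labels)
    stage_log.append({"stage": "detection", "n_segments": len(segs),
                      "elapsed_s": round(time.time() - t0, 2)})

    valid_s = mask_b.valid_duration
    bo = burst_occupancy(mask_b)
    met = channel_metrics(segs, valid_s, labels)
    met["bo_z"] = znorm_channels(met["bo"].to_numpy()) if len(labels) >= 2 else np.nan
    met = met[["channel", "bo", "bo_z", "n_bursts", "median_duration_s", "rate_hz"]]
    met.to_csv(out / "channel_metrics.csv", index=False)

    raster = epoch_bursts(mask_b.series, events, rec.fs, cfg.epoch_window,
                          valid=mask_b.valid, seam_samples=seam_samples, t0=rec.t0)
    bpi = compute_bpi(raster)
    ext = bpi_extrema(bpi, cfg.extrema_window)
    stage_log.append({"stage": "event_locked", "n_trials": raster.n_trials,
                      "n_dropped": raster.n_dropped})
    bpi_long = pd.DataFrame({
        "channel": np.repeat(labels, bpi.times.size),
        "time_s": np.tile(bpi.times, len(labels)),
        "raw": bpi.raw.ravel(),
        "bpi": bpi.bpi.ravel(),
    })
    bpi_long.to_csv(out / "bpi.csv", index=False, float_format="%.6g")
    pd.DataFrame({
        "channel": labels,
        "min": ext.min_value, "min_lat_s": ext.min_latency_s,
        "max": ext.max_value, "max_lat_s": ext.max_latency_s,
    }).to_csv(out / "extrema.csv", index=False)

    btr = intra_burst_touch_rate(mask_b.series, events, rec.fs, mask_b.valid, rec.t0)
    bbti_vals, n_w, n_wo = bbti(mask_b.series, events, rec.fs,
                                seam_times=seam_samples / rec.fs, t0=rec.t0)
    coup = coupling_table(labels, btr, bbti_vals, n_w, n_wo)
    coup.to_csv(out / "coupling.csv", index=False)
    segments_to_frame(segs).to_csv(out / "segments.csv", index=False, float_format="%.6g")

    manifest = {
        "tapburst_version": __version__,
        "seed": cfg.seed,
        "detection": asdict(cfg.detection),
        "epoch_window": list(cfg.epoch_window),
        "valid_duration_s": valid_s,
        "n_events": len(events),
        "stages": stage_log,
        "tables": ["channel_metrics.csv", "bpi.csv", "extrema.csv",
                   "coupling.csv", "segments.csv"],
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "metrics": met, "bpi": bpi, "extrema": ext, "coupling": coup,
        "segments": segs, "labels": labels, "manifest": manifest,
        "positions": rec.channel_positions,
    }


def run_group(results: list[dict], alpha: float = 0.05, n_boot: int = 1000,
              adjacency: np.ndarray | None = None, seed: int = 0,
              out_dir: str | Path | None = None) -> dict:
    """Pool per-participant bundles and run the population statistics.

    Scalar maps (BO-z, extrema, BTR-z, BBTI-z) → one-sample t + Bonferroni;
    BPI channel×time → cluster bootstrap.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 participants")
    labels = results[0]["labels"]
    for k, r in enumerate(results):
        if r["labels"] != labels:
            raise ValueError(f"participant {k} channel set differs from participant 0")

    def _stack(fn):
        return np.stack([fn(r) for r in results])

    scalar_maps = {
        "bo": _stack(lambda r: r["metrics"]["bo"].to_numpy()),
        "bo_z": _stack(lambda r: r["metrics"]["bo_z"].to_numpy()),
        "min_bpi": _stack(lambda r: r["extrema"].min_value),
        "min_lat": _stack(lambda r: r["extrema"].min_latency_s),
        "max_bpi": _stack(lambda r: r["extrema"].max_value),
        "max_lat": _stack(lambda r: r["extrema"].max_latency_s),
        "btr_z": _stack(lambda r: r["coupling"]["btr_z"].to_numpy()),
        "bbti": _stack(lambda r: r["coupling"]["bbti"].to_numpy()),
        "bbti_z": _stack(lambda r: r["coupling"]["bbti_z"].to_numpy()),
    }
    stat_maps = {name: bonferroni_map(v, alpha) for name, v in scalar_maps.items()}

    bpi_stack = _stack(lambda r: r["bpi"].bpi)  # (n, ch, time)
    if adjacency is None:
        pos = results[0].get("positions")
        if pos is None:
            raise ValueError("adjacency required (no channel positions available)")
        adjacency = adjacency_from_positions(pos)
    bpi_stat = cluster_bootstrap(bpi_stack, adjacency, alpha=alpha, n_boot=n_boot, seed=seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, sm in stat_maps.items():
            for c, lab in enumerate(labels):
                rows.append({"map": name, "channel": lab, "t": sm.t[c],
                             "p_raw": sm.p_raw[c], "significant": bool(sm.significant[c])})
        pd.DataFrame(rows).to_csv(out / "group_scalar_maps.csv", index=False, float_format="%.6g")
        times = results[0]["bpi"].times
        sig_frac = bpi_stat.significant.mean(axis=0)
        pd.DataFrame({"time_s": times,
                      "t_mean_over_channels": bpi_stat.t.mean(axis=0),
                      "sig_channel_fraction": sig_frac}).to_csv(
            out / "group_bpi_cluster.csv", index=False, float_format="%.6g")
    return {"scalar": stat_maps, "bpi": bpi_stat, "labels": labels}
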