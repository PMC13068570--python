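# tapburst

Transient β-burst analysis for continuous EEG recorded during self-paced
touchscreen behavior.

Beta-band (13–30 Hz) activity in sensorimotor cortex is not a sustained
oscillation but a train of brief (~100–300 ms) bursts.  When a person uses a
touchscreen at their own pace, the probability of being inside a burst dips
before each touch and rebounds afterwards — the burst-level analogue of
movement-related beta desynchronization and rebound.  `tapburst` implements
the full analysis chain for this phenomenon on continuous (un-epoched)
recordings, and ships a ground-truth synthetic-data generator so every stage
can be validated end to end without any real recordings.

## What it computes

- **Burst detection.** Complex Morlet wavelet power `P_c(f, t)` per channel
  over 13–30 Hz (1 Hz grid, 7-cycle wavelets).  A TF cell is burst-positive
  when `P_c(f, t) > 6 · median_t P_c(f, t)` (median over the whole valid
  recording, per channel and frequency); suprathreshold runs shorter than
  2 cycles (`2/f` s) are discarded.  Collapsing the binary TF matrix over
  frequency gives the binary burst series `b_c(t)`.
- **Burst occupancy (BO).** `BO_c = Σ burst durations / recording duration` —
  the fraction of searchable time channel *c* spends in bursts; optionally
  z-normalized across electrodes to expose topography.
- **Burst probability index (BPI).** The burst series epoched −3..+3 s around
  each touch, averaged over trials, baseline-corrected by subtracting the
  median of the time course.  Suppression and rebound are summarized by the
  minimum/maximum of the BPI in −1..+1 s and their latencies.
- **Intra-burst touch rate (BTR).** Touches that fall inside a burst divided
  by total burst time (touches/s).
- **Burst-behavior timing index (BBTI).**
  `log10(median Δt | interval contains a burst) − log10(median Δt | no burst)`
  over consecutive inter-touch intervals Δt.
- **Group statistics.** One-sample t tests against zero with Bonferroni
  correction for scalar channel maps; spatio-temporal cluster correction
  (sign-flip null of maximal cluster mass Σ|t|) for channel×time BPI images.
- **Synthetic sessions.** 1/f Gaussian background, Hann-windowed burst atoms
  with lognormal durations and calibrated SNR, lognormal inter-touch
  intervals (median 0.871 s), and two separable coupling mechanisms:
  a peri-touch gain on the burst rate, and thinning of touches during bursts.

## Worked example

```python
import tapburst as tb

cfg = tb.SynthConfig(n_channels=8, duration_s=240.0,
                     coupling=tb.Coupling(channels=(0, 1, 2, 3)), seed=7)
rec, touches, truth = tb.gen_session(cfg)

tf = tb.tf_decompose(rec)                    # Morlet power, 13-30 Hz
mask = tb.detect_bursts(tf)                  # 6x-median + 2-cycle rules
print(tb.burst_occupancy(mask).round(3))

raster = tb.epoch_bursts(mask.series, touches, rec.fs, valid=mask.valid)
ext = tb.bpi_extrema(tb.compute_bpi(raster))
print(ext.min_latency_s.round(2))
```

The cohort-scale version of this lives in `analysis/` as numbered driver
scripts.  Running them in order prints, for a 6-participant simulated cohort
(channels 0–3 carry the coupling):

```
$ python analysis/01_simulate_cohort.py
  pp00: 164 touches (median ITI 783 ms), 865 atoms, true occupancy 0.089 ...
$ python analysis/02_analyze_cohort.py
  pp00: 860 bursts, BO 0.068, median duration 137 ms, 164 touches
  ...
  min-BPI latency (s): [-0.19 -0.56 -0.73 -0.5  -0.23 -0.06  0.2  -0.45]
  max-BPI latency (s): [ 0.52  0.41  0.39  0.32 -0.02  0.25 -0.63 -0.22]
  BBTI:                [0.45 0.47 0.45 0.46 0.39 0.45 0.46 0.43]
$ python analysis/03_burst_behavior_report.py
         median_touch_to_onset_s  median_offset_to_touch_s
False                      1.397                     1.397
True                       1.433                     1.773
```

Read: on the coupled channels burst probability dips *before* the touch and
peaks *after* it (negative minimum, positive maximum latencies), while the
uncoupled channels show no consistent timing; BBTI is positive everywhere
(longer intervals are likelier to contain a burst — a sampling bias even
without coupling, see `docs/methods.md`) and slightly higher where touches
were thinned; and on coupled channels the last burst offset sits further
from the touch (1.77 vs 1.40 s).  At this small cohort scale (6
participants, 4 min each) the BTR contrast is within noise; the
validation experiments in `scripts/acceptance.py` measure it at proper
power.

A `tapburst` CLI wraps the same pipeline (`simulate`, `run-all`, `group`,
…); see `tapburst --help`.

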