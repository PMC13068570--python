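# Methods

## Burst detection

The detector follows the median-threshold lineage for transient beta events.
Each channel is decomposed with complex Morlet wavelets (default 7 cycles) on
a 1 Hz grid from 13 to 30 Hz (18 bins).  Per channel and frequency, the
threshold is `threshold_factor × median` of the power trace over all valid
samples of the whole recording (default factor 6).  Power must *strictly*
exceed the threshold.  Suprathreshold runs shorter than `min_cycles / f`
seconds (default 2 cycles) are deleted per frequency *before* the binary TF
matrix is collapsed across frequency into the burst series; no duration rule
is re-applied after collapsing, so a collapsed run can outlast any
single-frequency run.  Because the threshold is a quantile of each channel's
own power, detection is invariant to rescaling a channel.

Samples within half a wavelet length (5 Gaussian SDs, `5·n_cycles/(2πf)` s)
of either recording edge are flagged invalid per frequency and excluded from
both the median and detection.  The collapsed series' valid mask is the
across-frequency intersection, so "recording duration" in occupancy always
means the widest-wavelet-trimmed duration actually searched.

Tunable parameters (defaults): band 13–30 Hz, step 1 Hz; threshold factor 6;
minimum duration 2 cycles; wavelet width 7 cycles.  The wavelet width is the
one genuinely free choice: fewer cycles sharpen time resolution and shorten
noise runs, more cycles sharpen frequency resolution; 7 matches common
practice for beta-burst work.

## Behavior-based segment filter

Stretches whose distance to both the previous and the next touch exceeds
30 s are behaviorally inactive and may be removed before detection.
Recording edges count as having no event (infinite distance), so leading and
trailing inactivity is removable — the conservative reading of "both pre-
and post-event intervals".  Kept segments are concatenated; the index map
records every concatenation seam, and epochs, inter-touch intervals and
latency statistics that would straddle a seam are dropped rather than
spliced (splicing would fabricate long intervals).  Times are float seconds
everywhere; sample indices are 0-based with half-open `[onset, offset)`
intervals.

## Event-locked analysis

Epochs run −3..+3 s around each touch with *inclusive* endpoints (6001
samples at 1 kHz); trials leaving valid data are dropped, never padded.  The
BPI baseline is the median of the trial-averaged time course over the full
epoch — not a pre-stimulus window — so a symmetric modulation keeps the
baseline at the channel's typical occupancy.  Extrema are searched in
−1..+1 s; ties resolve to the first occurrence in time.  For touch↔burst
latencies, a touch inside an ongoing burst skips that burst in both
directions (the next onset is the *next* burst's onset, the previous offset
the *previous* burst's offset); the within-burst case is what BTR counts,
and double-counting it in both statistics would zero-inflate the latencies.

## Coupling statistics

BTR looks up the burst series at the sample containing each touch (floor);
a touch exactly on an offset sample is outside the burst (half-open rule).
BBTI classifies each consecutive inter-touch interval as WITH if any sample
strictly inside the *open* interval is ON; the open interval prevents a
single within-burst touch from driving both BTR and both flanking intervals'
classification.  BBTI is `log10` of the WITH-group median minus `log10` of
the WITHOUT-group median (for medians this equals the median of log
intervals).  BBTI carries a built-in sampling bias — longer intervals are
more likely to contain a burst even when bursts are independent of behavior
— so it must always be read against an independent-process baseline at
matched occupancy; the validation suite measures that baseline explicitly
(mean BBTI ≈ 0.37 under full independence at ~0.11 occupancy).

## Group statistics

Scalar channel maps (BO, extrema values/latencies, BTR, BBTI, and their
cross-electrode z-scores, sample SD with n−1) use one-sample t tests against
zero, two-sided, Bonferroni-corrected.  Channel×time BPI images use a
cluster-based correction: cells with raw p below the cluster-forming
threshold (default 0.05) are grouped into connected components — channel
neighbors at the same time point, adjacent time points at the same channel —
and each cluster is scored by its mass Σ|t|.  The null of maximal cluster
mass is built by randomly sign-flipping each participant's map (default 1000
resamples); a cluster is significant when its mass exceeds the 1−α quantile.

Sign-flipping was a deliberate design choice.  The alternative — centering
each participant at the group mean and resampling participants with
replacement — looks equivalent but is not: at n≈20, resamples containing
duplicated participants occasionally produce near-zero cell variances and
hence extreme |t| values, which fatten the null's tail (95th percentile of
max mass ~18.7 versus ~11.6 for the true sampling distribution in a
16-channel × 200-sample pure-noise benchmark) and drive the realized
family-wise error toward zero.  The sign-flip null is exact under the
symmetric null hypothesis and measures FWER ≈ 0.04–0.07 at α = 0.05 in the
same benchmark.  The centered bootstrap remains available as
`variant="centered_bootstrap"`.  Channel adjacency comes from sensor
positions (distance threshold targeting a median of 4–8 neighbors) or is
supplied explicitly; it must be symmetric and irreflexive.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes, with defaults chosen as a realistic single-session scale:

- **Background**: independent per-channel `1/f^α` Gaussian noise (α = 1),
  RMS-normalized.  No volume conduction, line noise, or artifacts.
- **Bursts**: Hann-windowed sinusoidal atoms — bounded support makes
  ground-truth durations exact — at Poisson occurrence times
  (0.5 Hz/channel), frequencies uniform in 13–30 Hz, durations lognormal
  (median 0.2 s, log-SD 0.3).  Rate × mean duration gives ~0.11 occupancy,
  the scale reported for scalp EEG.  The occurrence time is the atom
  *center*: any rate modulation acts on when the burst event happens, so the
  suppression of the resulting ON series sits symmetrically inside the gain
  window instead of smearing one atom-duration forward (with onset-timed
  modulation the expected burst-probability trough would end exactly at the
  touch and the sign of its latency would be decided by noise).  Atom
  amplitude is calibrated empirically so the peak Morlet power at the atom's
  nearest analysis frequency equals `snr ×` the background's median power
  there (default snr 8).
- **Touches**: a renewal process with lognormal inter-touch intervals,
  median 0.871 s and log-SD 0.977 (chosen to match a ~1.24 s interquartile
  range), the typical cadence of smartphone interaction.
- **Coupling**, two separable mechanisms so burst-rate effects and
  touch-hazard effects can be tested independently: (i) a peri-touch gain on
  the burst-onset rate (suppression 0.3× in −0.8..0 s, rebound 1.5× in
  0.2..1 s; suppression wins where windows overlap; implemented by Poisson
  thinning), and (ii) thinning of touch candidates while a burst is ON
  (hazard × `touch_gain`).  All randomness flows from one master seed via
  `numpy.random.SeedSequence` spawning; identical seeds reproduce sessions
  bit-for-bit.

## Detector operating point — a known limitation

Against this generator the detector's recovery of individual atoms is
interference-limited.  The background's Morlet coefficient is complex
Gaussian, with mean power ≈ 1.44× its median; at the atom peak the measured
power is `|a + n|²`, and with `a² = 8 × median` roughly a third of atoms are
pushed below the 6×-median threshold by destructive interference alone.
Conversely, Gaussian 1/f background with *no* atoms yields ≈ 0.27 detections
per second per channel (occupancy ≈ 0.037) after the 2-cycle rule and the
18-bin collapse — such threshold excursions are intrinsic to the method, not
a bug.  Measured at snr 8, 0.2 s median durations: recall ≈ 0.54 and
precision ≈ 0.6 under a 50%-overlap matching rule (each atom must be half
covered by detections; each detection half covered by atoms).  Recovery
becomes near-perfect only for atoms whose realized peak sits far above the
threshold (e.g. snr ≳ 30).  Consequently detected occupancy underestimates
generative occupancy at moderate SNR, and single-burst-level claims should
be treated with more caution than the occupancy/BPI/coupling aggregates,
which average over many events.  Timing-level analyses (BPI, BTR, BBTI) are
therefore validated on the ground-truth burst series directly, separating
detector performance from event-locked inference.

What passing the synthetic validation does *not* show: robustness to
artifacts, volume conduction, non-stationary background spectra, or
non-Poisson burst dynamics — none of which the generator emulates.

## Problem sizes used in the validation suite

Detector/reference agreement uses 100 random TF matrices (≤3 channels,
≤5 frequencies, ≤2000 samples).  Recovery and coupling experiments use
8-channel, 10-minute sessions at 1 kHz; null calibrations use 50–100
simulated sessions; the FWER benchmark uses 200 pure-noise groups of 20
participants (16 channels × 200 samples) at 500 resamples.  These sizes give
Monte-Carlo standard errors comfortably below the asserted margins.
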