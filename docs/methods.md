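# Methods

This note documents the models and procedures `spheromea` implements,
the tunable parameters and their defaults, the design choices made
where the analysis convention was genuinely open, what the synthetic
generator does and does not emulate, and known limitations.

## Conventions

Voltages are microvolts throughout; times are seconds, float, zero-based
from recording start; spatial coordinates are micrometres. The standard
layout is the 60-site 8×8-minus-corners TiN grid (30 μm electrode
radius, 200 μm pitch) with site 15 as internal reference, leaving 59
recording electrodes. Recordings live in a self-describing HDF5
container (one dataset per channel under `/recording/analog`, layout
and culture metadata embedded, with an optional JSON sidecar).

## Spike detection

Raw traces are band-passed at 250–3000 Hz with a second-order
Butterworth filter applied forward–backward (`sosfiltfilt`). Zero-phase
filtering keeps detected peak times unshifted; the price is that the
effective roll-off doubles relative to a single pass.

The background-noise scale is estimated per electrode as
σ = median(|x|)/0.6745 over the filtered trace — consistent with the SD
under Gaussian noise and nearly insensitive to the spikes riding on it,
which would inflate a plain SD. Detection is double-sided at ±kσ with
k = 5: events are local extrema of |x| above threshold, separated by a
1 ms dead time, aligned to the signed absolute extremum, with a
−1/+2 ms waveform window. The dead time and window are not dictated by
any convention; they bracket extracellular spike widths at 32 kHz. The
threshold is applied to the whole trace (no sliding re-estimation).
A flat trace (σ = 0) refuses detection rather than dividing by zero.

## Spike sorting

Waveforms of one electrode are mean-centred and projected onto their
top two principal components. k-means (k-means++ init, 10 restarts,
seeded) is run for k = 1…6 and the mean within-cluster radius r(k)
(mean distance of points to their assigned centroid) recorded. The
unit count is the "knee" of this curve: fit log r(k) against log k by
least squares; the candidate is the k with the most negative residual,
accepted only if the relative drop r(k−1)→r(k) exceeds 20%, else k = 1.

Two caveats are worth knowing. First, the 20% guard is marginal for a
single *isotropic* Gaussian cloud, whose k-means radius drops hover
around 20%; occasional over-selection (k = 2–3 for one true unit) is
inherent to radius-knee rules. Second, a single unit with amplitude
variability produces an *elongated* score cloud, which k-means will
happily split. Both failure modes split one spike train into
interleaved sub-trains; spike-count-weighted population metrics
(burstiness, network burstiness, firing rate) are essentially
unaffected, and the per-pair correlation analysis excludes
same-electrode pairs exactly because such splits produce spurious
structure. Fewer than two events on an electrode skips sorting.

## Burst detection (adaptive log-ISI threshold)

Per unit, ISIs are histogrammed on a uniform base-10 log grid, 10 bins
per decade over [1 ms, 100 s] (ISIs outside are clipped in). A bursting
unit shows a bimodal histogram: a short-ISI (intra-burst) mode and a
long-ISI (inter-burst) mode. Peaks are located after Gaussian smoothing
(σ = 1.5 bins), keeping only peaks reaching 5% of the tallest bin; a
peak pair qualifies when its void parameter
1 − p(valley)/√(p(peak₁)·p(peak₂)) is at least 0.7 and the first peak
lies below 100 ms. The threshold is the bin centre of the valley of the
best-separated qualifying pair. Without a qualifying pair the threshold
falls back to 0.1 s; a threshold above 0.1 s switches on the enclosure
rule below.

The smoothing σ and the 5% peak floor are this package's
operationalization, calibrated once so that sampled unimodal (Poisson)
trains mostly fall back while genuinely bimodal trains are never
missed; both are exposed in `RunConfig`. Sampling noise on an
exponential ISI tail can still occasionally pass the void test; the
resulting few-millisecond thresholds yield essentially no 3-spike runs,
so the downstream effect is nil.

Bursts are maximal runs of consecutive spikes with every ISI at or
below the threshold. Runs with fewer than max(3, ⌈N/3000⌉) spikes are
discarded (N = the unit's total spikes; ⌈·⌉ because the quantity is a
count). Under the enclosure rule, a run is kept only if it fully
contains a run detected at the fixed 0.1 s threshold that itself passes
the size floor. Burst intervals are closed [first spike, last spike].
Burstiness is the fraction of the unit's spikes inside its bursts.

## Network bursts

A count series on a uniform 1 ms grid records how many units are inside
a burst at each sample. One element per raw 32 kHz sample would be
mathematically equivalent for intervals bounded by spike times (which
are far coarser than 1 ms apart) at 32,000× the memory; Δt = 1 ms is
used throughout. The NB threshold is one third of the mean of the
samples at or above the series' 90th percentile. Candidate NBs are
maximal runs with counts ≥ max(threshold, 1) — the floor of 1 prevents
a zero threshold from labelling silence. A candidate keeps all spikes
of all units inside its interval as its spike count and survives if
that count reaches max(10, ⌈total bursting spikes on the array/300⌉).
NB duration is the supra-threshold run length, not the span of member
bursts. Note that raising the threshold can split one run into two, so
NB *count* is not monotone in the threshold; the monotone invariant is
that the supra-threshold time support is nested.

Network burstiness of a unit is the fraction of its spikes inside any
NB interval. NB counts are reported per 10 minutes. The activity map
averages the rectified filtered signal per electrode over a window, for
grid visualization of array-wide events.

## Activity metrics

A unit is **active** above 10 spikes/min (strict); the mean firing rate
averages spikes/s over active units only. **Entropy** is Shannon's
−Σ pᵢ ln pᵢ over the log-ISI histogram bins (natural log; the base only
rescales, so values are reported in nats; the bound is ln N for the
N-bin histogram shared with burst detection). **Rate vectors** hold
log₁₀ of the instantaneous rate 1/ISI, piecewise constant between
consecutive spikes, sampled directly on a 320 Hz grid (identical to
building at 32 kHz and decimating, for piecewise-constant signals);
before the first and after the last spike the adjacent interval's value
is extended, since any constant fill would inject spurious correlation
at the recording edges. Pairwise correlation is the zero-lag Pearson
coefficient between rate vectors of active units; same-electrode pairs
are excluded (sorting artifacts produce spurious negative correlation
there), as are zero-variance vectors; array-level summaries average
included pairs only.

## Imaging

Phase-contrast montages show clusters as red-shifted (brownish) blobs
on a paler background, with electrodes nearly black. The chain is:

1. **Inpainting.** Electrode pixels (grayscale exactly 0 or below one
   SD under the image mean, dilated by 2 px) are filled per channel by
   iterated 4-neighbour averaging to convergence — a discrete harmonic
   fill obeying the maximum principle.
2. **Hue map.** Per-pixel red/blue ratio (denominator floored at one
   8-bit grayscale unit), so clusters score *high*; a configuration
   flag inverts the ratio for the opposite convention. The two
   descriptions of this ratio in circulation disagree on orientation;
   only red/blue is self-consistent with above-mean thresholding of
   red-shifted clusters, which is why it is the default rather than a
   silent resolution.
3. **Spatial band-pass.** Difference of Gaussians with σ = 15 μm
   (rejects single cells and speckle) and σ = 300 μm (rejects
   illumination gradients). The cutoffs are this package's choice.
4. **Segmentation.** Pixels above mean + 1.4 SD, then one 3×3 binary
   erosion to drop isolated suprathreshold pixels. Because the
   threshold is *relative*, a cluster-free montage still segments the
   upper tail of its noise (Φ(−1.4) ≈ 8.1% pre-erosion, ≈ 5% after);
   cluster ratios near that floor are not evidence of clusters.
5. **Cluster ratio** = segmented pixels / total pixels, optionally
   normalized to the first imaging day of an MEA.
6. **Clusterness.** Per electrode, the Gaussian-weighted mean of the
   hue map in a 31 × 31 μm window centred on the electrode, with the
   window edge at one SD (σ = 15.5 μm); the window is read as
   micrometres, not pixels. Electrodes outside the image are flagged
   missing.

The μm/px scale is required metadata; the package refuses to guess it.

## Group statistics

All intervals are percentile bootstrap CIs: 6000 resamples with
replacement, interval = 5th–95th percentiles of the resampled means
(linear interpolation between order statistics; seeded, with the seed
recorded in every report). Electrodes are grouped by burstiness:
`nonbursting` (no detected bursts), `top5` (at or above the 95th
percentile of bursting electrodes, boundary ties included), `p1_3`
(1st–3rd percentile inclusive), `other`. MEAs are stratified per
recording date into NB-duration tertiles and correlation median splits,
sorted ascending with ties broken by MEA id; when the count does not
divide evenly the lower groups take the remainder (7 → 3/2/2); dates
with fewer MEAs than groups are skipped and logged. Percentile grouping
is computed on data pooled across MEAs per date.

## Synthetic data

The recording generator draws each unit as an inhomogeneous Poisson
process with a 2 ms refractory period and piecewise-constant rate: an
asynchronous baseline (0.5 Hz default, the sparse regular firing of
young cultures), elevated rate (80 Hz default) inside per-unit burst
epochs, and inside array-wide NB epochs for participating units — the
three activity regimes the pipeline is built to quantify. Each spike
renders a 1.5 ms biphasic (difference-of-Gaussians) template with 10%
amplitude jitter onto Gaussian noise (3 μV SD default); template
amplitudes default to 24 μV = 8× noise SD so 5σ detection operates well
above threshold. Two units on one electrode get opposite dominant
polarity, making PCA separation well-posed. The canonical validation
scenario (`reference_recording_scenario`) is five such units on four
electrodes — two sharing electrode 12 — for 600 s at 32 kHz with eight
1.2 s NB epochs.

The image generator renders red-shifted discs (logistic edge, 5 μm
softness — sharp at the 2.5 μm/px scale used) on a pale textured
background with near-black electrode discs; the true cluster mask
(pixels within the design radius) is returned alongside. The canonical
scene is three clusters of 80–100 μm radius on a 1.8 × 1.8 mm canvas.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: electrode-to-electrode noise differences
and correlated (shared-mode) noise; waveform drift, bursts' amplitude
adaptation and spike collisions within an electrode; biological
variability of burst shape; phase-contrast halos, stitching seams and
uneven illumination beyond a smooth gradient; cluster movement between
imaging and recording. Recovery results on synthetic data bound the
pipeline's algorithmic correctness, not its robustness to those
artifacts.

## Validation problem sizes

The end-to-end check runs the canonical 5-unit, 600 s, 32 kHz scenario;
oracle sweeps use 10⁴ random spike trains (≤ 50 spikes) for the burst
detector and 10³ random vectors for the NB threshold; bootstrap
coverage uses 500 simulated normal datasets of n = 100 at B = 6000
(n = 100 keeps the interval's true coverage near its nominal 90%, and
the Monte-Carlo SE of the coverage estimate ≈ 1.3%); imaging recovery
uses three seeded scenes plus a noise-only field for the tail fraction.

## Known limitations

- No template matching, artifact blanking, cross-electrode sorting,
  drift correction or manual curation; sorting quality is bounded by
  PCA + k-means on a per-electrode basis.
- Burst-shape classification, superbursts, burst propagation/latency
  and sub-250 Hz field-potential analysis are out of scope.
- The relative segmentation threshold makes cluster ratios near the
  ~5% noise floor uninterpretable (see Imaging above).
- The knee rule can over-split units; treat unit counts as putative.
- Bootstrap CIs are percentile intervals of the mean; no hypothesis
  tests or mixed-effects modelling are provided.
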