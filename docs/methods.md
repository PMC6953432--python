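# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the design decisions taken where the method left room, and
what the synthetic test bench does and does not establish.

## Oscillatory event detection

Neonatal prefrontal activity is modeled as silence interleaved with
band-limited oscillatory events. Detection operates on the 1–100 Hz
band-passed trace: a centered sliding RMS envelope (window 200 ms, hop one
sample) is thresholded at μ + k·σ, where μ and σ come from a least-squares
Gaussian fit to the envelope's amplitude histogram (100 bins over
[0, max]). Supra-threshold crossings closer than 200 ms are merged into
one event (merge first, then the duration gate), and an event is kept only
if it lasts more than 1 s.

Numerical choices:

- **Histogram fit range.** The Gaussian is fitted over the full histogram
  range. Fitting only up to the histogram mode was evaluated and rejected:
  a truncated fit to the left flank of the (right-skewed) envelope
  distribution underestimates the noise spread by roughly half, placing
  the threshold ~1 SD above the silent floor; on default synthetic
  recordings this cost precision (0.86 vs 1.0) and tripled boundary error.
  The fit is initialized at the histogram peak with σ from its half-width
  and bounded to the data range, so it cannot diverge on sparse or skewed
  histograms.
- **Duration gate in supra-threshold time.** "Lasting more than 1 s" is
  measured as the total time the envelope is above threshold within a
  merged event — bridged sub-200-ms gaps join oscillations but are not
  themselves oscillating time — corrected by one RMS window, because the
  centered window smears each crossing outward by up to half a window.
  Reported event boundaries remain at the measured crossings. Without the
  correction, a strong 0.8-s burst is reported in ~20% of noise
  realizations; with it, exclusion holds whenever the background around
  the burst is actually silent.
- **k (threshold multiplier), default 2.** The single most
  result-sensitive free parameter; exposed everywhere and reported in
  outputs. Raising k can only reduce the number of detections
  (monotonicity is tested).
- The RMS window default of 200 ms was kept after measuring 100/150/200 ms:
  shorter windows produce a noisier envelope and were worse on every
  recovery metric.

## Spectral analysis

Power is defined only over oscillations: each detected event contributes
⌊duration⌋ whole 1-s windows from its onset, and Welch's method averages
non-overlapping 1-s Hann segments over the concatenation (1 Hz
resolution). Band powers integrate the PSD by the rectangle rule
(Σ psd·Δf over bins with lo ≤ f < hi). The half-open convention means
theta/beta/gamma partition 4–100 Hz exactly — disjoint bands are additive
and a tone at a shared edge (30 Hz) is counted once, in the upper band.

Ramp stimulation trials are summarized by the modulation index
(stim − pre)/(stim + pre) of band power between the 1.5 s before ramp
onset and the last 1.5 s of the ramp (Welch, two 0.75-s segments per
window). The symmetric bounded form is the field's standard contrast; it
is scale-invariant and lies in [−1, 1].

## Spike detection and firing statistics

MUA spikes are troughs in the 500–5,000 Hz band below −5·SD whose
prominence (on the inverted trace) exceeds half the trough depth. The SD
is the plain standard deviation of the whole trace by default (a
median-based robust estimate is available behind a flag, since heavy
spiking inflates the plain SD). A 1-ms dead time prevents double-counting
multiphasic waveforms. Detection is invariant to amplitude scaling.

ISI histograms use 2-ms bins with centers on the 2-ms grid
(10, 12, …, 500 ms; edges offset half a bin so a preferred interval lying
on the grid falls mid-bin), normalized by the total number of intervals;
only the 10–500 ms range is returned, so the returned mass may sum to
less than 1.

## Spike–field coupling

Band phase is the angle of the analytic signal (Hilbert transform) of the
zero-phase band-passed LFP; phase 0 at signal maxima. PPC is the mean
cosine of all pairwise phase differences, computed through the closed form
(|Σe^{iθ}|² − n)/(n(n−1)); the O(n²) pairwise sum is kept as a test
oracle. For von Mises phases with concentration κ the expectation is
(I₁(κ)/I₀(κ))², independent of spike count — the estimator is checked
against this at κ ∈ {0, 1, 2, 4}.

Spike-triggered relative power contrasts the Hann-tapered PSD of the
200-ms window centered on each spike with the average PSD of two
pre-spike baseline windows (100–300 and 200–400 ms before the spike;
their overlap is intentional and their PSDs, not samples, are averaged).
A 200-ms window admits a single spectral segment (5 Hz resolution), whose
per-frequency values are approximately exponential-distributed; the
per-spike ratio therefore has a large positive bias (E[1/P_baseline] of a
two-segment average far exceeds 1/E[P_baseline]; measured +1.64 on
stationary noise). The default consequently averages spectra over spikes
before forming the ratio, which is unbiased under the null; the per-spike
variant remains available (`per_spike_normalize=True`). Pooling over
spikes is the default aggregation; per-unit averaging can be built from
per-unit calls.

## Microglia morphometry and engulfment

Counting: maximum-intensity projection → 3×3 median despeckle → Gaussian
blur (σ = 2) → triangle automatic threshold → connected components larger
than 150 px. Morphology: Otsu threshold on the projection, candidates
between 200 and 1,500 px, a 110×110 px ROI centered on each centroid;
cells touching the ROI border or sharing it with another candidate are
discarded (the automated analog of visual exclusion). Features: area,
perimeter, eccentricity (equivalent-ellipse), spread (mean distance from
the center of mass to the 8 extremal boundary points), roundness
4πA/P².

- **Perimeter estimator.** The marching-squares contour at the 0.5 level,
  lightly smoothed (7-point circular moving average) before summing
  segment lengths. Pixel-walk estimators with √2 diagonal weights
  overestimate smooth boundaries ~5% (a disk of radius 40 px scores
  roundness 0.91); Crofton estimators fix disks but bias squares. The
  smoothed contour walk gives roundness 0.998 for the disk, π/4 within
  0.01–0.04 for squares, and ellipse perimeters within 0.3% of analytic.

Engulfment: the microglia channel is binarized by 3D hysteresis (0.1/0.5
of the intensity range, 26-connectivity) followed by a 3×3×3 median
filter. VGLUT1 stacks are background-subtracted (rolling-ball radius 2,
implemented as a per-plane grayscale opening), despeckled, maximum-filtered
(radius 2, per plane), Otsu-thresholded and watershed-split on the
anisotropy-aware distance transform; components are size-gated to 100–500
px. A punctum is engulfed only if 100% of its voxels lie inside the cell
mask. Distal volume counts mask voxels farther than 7 µm from the center
of mass, with physical (anisotropic) distances; defaults are 0.103 µm
pixels and 0.75 µm z-steps.

## Classification

Per-animal feature vectors (beta/gamma oscillation power, superficial
log₁₀ firing rate, spike-triggered relative power in beta and gamma) are
classified by a pipeline of quantile transformation (uniform output),
mutual-information percentile feature selection, and kNN. The dataset is
split 500 times into a stratified 2/3 train / 1/3 validation set;
hyper-parameters (quantiles {5, 10, 25}, percentile {40, 60, 80, 100},
neighbors {1, 3, 5, 7}, weights {uniform, distance}, leaf size {10, 30})
are tuned per repetition by stratified inner 3-fold grid search on the
training set; the median held-out accuracy is reported. Stratification
prevents empty-class folds at cohort sizes around 30.

The inner search computes each fold's transform and mutual-information
scores once per quantile setting and evaluates the whole kNN sub-grid
from a single 7-neighbor query (predictions for smaller k are prefixes of
the sorted neighbor list; leaf size never changes predictions) — the
selected parameters are identical to exhaustively fitting every
combination, at a fraction of the cost. Ties are broken toward the first
combination in grid order, and kNN class ties toward the smallest class
index, so results are seed-reproducible. The 500 refitted pipelines form
an ensemble that votes on held-out animals; a t-SNE embedding with a
1-nearest-neighbor class field over a dense grid visualizes the decision
space.

## Robust statistics

All group comparisons use 20% trimming. The two-sample statistic is
Yuen's: trimmed-mean difference over the standard error from winsorized
variances, d_j = (n_j−1)s²_{w,j} / (h_j(h_j−1)) with h_j the number of
untrimmed values. The paired version applies the one-sample Yuen
statistic to difference scores. The one-way statistic is the
heteroscedastic Welch-type F for trimmed means. Null distributions come
from resampling trimmed-mean-centered groups (5,000 bootstrap repetitions
by default); p-values are two-sided with +1 smoothing in numerator and
denominator (so p ≥ 1/(B+1)); CIs are percentile intervals of the
bootstrapped trimmed-mean difference. Pairwise post hoc contrasts are
percentile-bootstrap CIs without additional multiplicity correction — the
correction convention is left to the caller. The bootstrap is fully
vectorized (resample → row-sort → trimmed/winsorized moments on the
sorted matrix), which keeps 1,000-simulation calibration runs in seconds.
Both tests calibrate to a measured type-I error of ~0.047 at nominal
0.05 (4,000-simulation estimate).

## The synthetic test bench

The generators produce the statistical structure the pipeline assumes,
with stored truth:

- **Recordings**: 1/f¹ Gaussian background (12 µV RMS broadband; ~6.5 µV
  within 1–100 Hz), 4 events/min, durations uniform on 1.5–4 s, peak
  amplitudes uniform on 60–120 µV. Bursts are mixtures of three random
  sinusoids per carrier band (theta 4–12 Hz, beta 15–40 Hz) with a
  flat-top envelope and 200-ms Hann-shaped edge tapers — edges stay sharp
  enough that detector boundary error is a meaningful quantity, while
  onsets remain click-free. Events are shared across channels (volume
  conduction in the small neonatal tissue volume) with independent noise.
- **Spike trains**: inhomogeneous Poisson, rate elevated 5× during
  events, with the overall mean rate solved to equal the requested
  10^log₁₀ rate. Group defaults use the reported cohort log₁₀ rates
  (control superficial −0.61 ± 0.04 vs GE −2.1 ± 0.1; deep −0.95 / −1.3),
  with log base 10 assumed (10^−0.61 ≈ 0.25 spikes/s is physiologically
  plausible for neonatal cortex). Phase locking is implemented by
  thinning candidate spikes against the instantaneous carrier-band phase
  with acceptance ∝ the von Mises density, so the spike-phase law is
  exactly von Mises and the marginal rate is unchanged.
- **Ramp sessions**: 3-s ramps flanked by ≥1.5-s windows; evoked
  beta-band LFP amplitude grows linearly with light power. Tuned mode
  draws during-ramp ISIs from N(60, 4) ms — a 16.7 Hz population rhythm;
  untuned mode fires Poisson at 2 spikes/s during the ramp. The untuned
  rate is derived from the defining requirement that exponential ISIs
  show no structure across the 10–500 ms analysis range (decay ratio
  max/median < 3 requires rate ≲ 2.5/s); it still exceeds the 0.5/s
  baseline.
- **Feature cohorts**: group-specific multivariate Gaussians whose means
  (and SDs) interpolate between the grand mean and the condition values
  with `effect_scale`; at 0 the group distributions are identical, at the
  default 1 the groups are separated by ~4–7 pooled SDs per feature
  (mirroring the strong reported condition differences).
- **Image stacks**: non-touching ellipsoidal cells (placement respects
  the 110×110 ROI isolation rule and image borders) and puncta with a
  sharply peaked intensity profile exp(−3d²) — like diffraction-limited
  synaptic puncta. The peaked profile matters: a flat-top blob is leveled
  entirely by radius-2 rolling-ball background subtraction (the opening
  reproduces any plateau wider than the ball). With it, the full chain
  recovers 13/13 planted puncta with mean volume within ~5–10% of truth
  and exact engulfment counts.
- **Behavior tables**: per-animal discrimination ratios drawn around the
  group mean and inverted exactly into novel/familiar interaction times.

What the bench does **not** emulate: spike waveform diversity and
overlap (no spike sorting is modeled), non-stationary background
(anesthesia depth, age progression P4–6 vs P8–10), electrode drift or
movement artifacts beyond the shared-component model, microglial process
arborization (cells are smooth ellipsoids; Sholl-type measures are out of
scope), and optical PSF/noise physics of real confocal stacks. Passing
tests therefore certify the estimators and rules against their stated
models, not performance on real recordings or images.

## Problem sizes

The test suite and the acceptance script run at desk scale: 5–20 simulated
minutes of LFP at 1 kHz, 10 minutes of 32 kHz noise for the spike-detector
floor, 2,000-spike phase samples (averaged over 10 draws so the
Monte-Carlo error of the check sits well below the 0.02 tolerance),
cohorts of 60 animals with 100 CV repetitions, and 1,000-simulation /
1,000-bootstrap calibration runs. Chance-level classifier accuracy is
measured by pooling repetitions over three independent zero-effect
cohorts, because a single 60-animal cohort's accidental structure moves
its median accuracy by ±0.1.

## Known limitations

- The RMS-histogram threshold assumes the silent background dominates the
  recording; recordings that are mostly active would push the fit toward
  the event mass.
- A 0.8-s burst adjacent to a genuine background elevation can still be
  reported as an oscillation: detection cannot distinguish a short burst
  riding on elevated background from a longer oscillation. The exclusion
  guarantee holds for bursts in locally silent background.
- Engulfment requires strict 100% voxel overlap; a single boundary voxel
  outside the (median-filtered) cell mask disqualifies a punctum, so
  segmentation smoothing choices propagate directly into counts.
- Hyper-parameter re-tuning in every CV repetition is expensive at the
  default 500 repetitions (~minutes per cohort); the efficient inner
  search mitigates but does not remove this.
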