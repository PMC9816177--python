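# Methods

`crossadapt` analyzes how rapid adaptation to one visual feature (an
oriented grating or a colored patch) reshapes the coding of an
orthogonal feature in a visual cortical population. It implements the
full analysis chain — image patch feature scoring, scanpath
simulation, eye-event segmentation, circular tuning statistics,
population decorrelation and decoding — together with a synthetic-data
generator that produces every input with known ground truth. This note
documents the models, the parameter choices and the numerical
decisions.

## Synthetic populations

Spike counts are generated from a von Mises tuning model with a
low-dimensional shared-variability structure. Neuron *i*'s mean rate
at stimulus angle θ (degrees) is

    m_i(θ) = b + A · exp(κ_i [cos(p(θ − μ_i)) − 1]),

with baseline *b* (spikes/s), amplitude *A* (spikes/s), concentration
κ_i and preferred angle μ_i drawn uniformly over the stimulus period.
The period multiplier is p = 1 for color (a 360° hue circle sampled at
16 angles in 22.5° steps) and p = 2 for orientation (a 180° circle in
11.25° steps), so orientation tuning is properly 180°-periodic. A
configurable fraction of neurons is untuned (κ = 0).

Per-trial rates add a shared latent term and private noise:

    r_trial = m(θ) + L z + ε,   z ~ N(0, σ_s² I_d),  ε ~ N(0, σ_p² I),

where L has unit-norm columns (d latent dimensions). Counts over the
analysis window are the rates integerized and truncated at zero —
windowed counts are all the downstream statistics consume, so no point
process is simulated. The closed-form trial covariance
σ_s² L Lᵀ + σ_p² I is exposed for parameter-recovery tests (verified
empirically to 5% Frobenius error at 10,000 trials).

Adaptation acts through three knobs applied to the adapted condition:
a multiplicative rate gain, an additive concentration boost (tuning
sharpening), and a multiplier in (0, 1] on the shared latent s.d.
(population decorrelation). Both conditions have equal trial counts
per stimulus.

**Defaults** (one synthetic "session"): 30 neurons, 16 stimuli × 28
trials/condition (≈450 trials per condition, matching the recorded
sessions), b = 10, A = 20 spikes/s, κ = 1.5, 30% untuned, d = 3,
σ_s = 15, σ_p = 10 spikes/s, 0–200 ms count window. The noise scale is
chosen so trial-to-trial shared fluctuations are comparable to
stimulus-driven modulation, the regime cortical recordings show; in a
signal-dominated regime the projected-PC statistic would be governed
by tuning changes rather than shared variability, which is not what it
is meant to measure. The canonical effect configuration
(`adaptation_effect_config`) sets gain 0.967 (a −3.3% rate change),
κ-boost 0.5 (mean selectivity change ≈ +0.04) and shared shrink 0.7,
mirroring the reported effect directions and magnitudes.

A time-resolved mode emits Poisson counts in 5-ms bins with the tuned
response switching on at a configurable latency (shifted further under
adaptation); it exists solely to exercise the sliding-window tuning
analysis. Poisson is used there because integerizing a truncated
normal is meaningless at per-bin expectations ≪ 1.

## Synthetic scenes and eye traces

Scenes are RGB images on a gray (or achromatic 1/f-noise) background
holding non-overlapping patches: achromatic sinusoidal gratings
(oriented) and uniform color fields (colored), with per-patch ground
truth. Placement is rejection sampling with bounded retries and full
layout restarts; geometrically infeasible requests raise a placement
error. These surrogates deliberately lack the continuous orientation
and color statistics, occlusions and luminance structure of natural
photographs — tests passing on them validate the bookkeeping and the
classifiers' behavior on unambiguous patches, not performance on
natural images.

Eye traces are 1 kHz gaze samples over a four-quadrant display (gray
control, adapter, two test stimuli). Fixation durations are
log-normal; saccades follow minimum-jerk position profiles whose peak
velocity obeys a linear main sequence (80 + 45·amplitude deg/s, safely
above the 100 deg/s detection threshold), fixational drift is a small
random walk (≈5 deg/s apparent velocity), and microsaccades are 0.25°
minimum-jerk excursions over 12 ms (peak ≈ 39 deg/s, below threshold
by construction). Consecutive random fixations never revisit the same
quadrant, since a within-quadrant saccade can be small enough to fall
below the velocity threshold. The pupil series is a slow AR(1). In
full free-viewing sessions, spike counts are defined per fixation
episode: test-quadrant fixations draw from the tuned model at the
quadrant's stimulus angle, with the adapted parameter set when the
preceding fixation was on the adapter and the unadapted set after the
gray control.

## Image features

Brightness is the BT.601 luma of the RGB image. The Sobel gradient
(3×3 kernels, reflected borders) yields per-pixel magnitude
√(Gx² + Gy²) and edge orientation — the gradient direction rotated by
90° and collapsed to [0, 180), with the sign of the row derivative
flipped so orientation is measured counterclockwise in display
coordinates (a brightness ramp along x scores 90°, i.e. vertical
contours). Patch orientation content is a 36-bin (5°) histogram of
edge orientations weighted by magnitude; the orientation selectivity
index is the normalized first circular moment on the doubled-angle
circle,

    OSI = |Σ_b h_b e^{2iθ_b}| / Σ_b h_b,

and the mean orientation is half the argument of the same sum. OSI is
invariant to brightness scaling and equals 0 for an all-zero histogram
(mean orientation undefined, reported as NaN).

A patch is **colored** when (a) each smoothed 256-bin channel
histogram peaks at least Δ = 30 away from 0 and 255, (b) the three
peak locations do not all sit within one ±Δ band (max − min > Δ, the
gray exclusion), and (c) the orientation signal is not significant. It
is **oriented** when the Rayleigh test on the doubled-angle weighted
histogram is significant at 0.05, the sub-window OSI distribution has
at most one peak, and (a)–(b) do not hold. Everything else — and any
patch with a multi-peaked OSI distribution — is **neither**. Channel
peaks use a width-5 moving average with ties broken toward the lower
value, so a single-valued channel reports its value within the
smoother half-width. For the Rayleigh test the histogram weights are
rescaled to sum to the pixel count (one effective observation per
pixel); note that discrete derivative kernels are mildly anisotropic,
so on featureless noise this test can reject more often than its
nominal level — on structured backgrounds the orientation gate is
conservative by design, not a calibrated test. The multi-orientation
exclusion tiles the patch 5×5, computes each tile's OSI from
pixel-level resultants, bins the 25 values into 10 bins and counts
local maxima exceeding 3 s.d. above the mean bin count; with 25
sub-windows this threshold rarely triggers, making the exclusion
deliberately conservative.

Feature maps slide a 50×50 window in 10-px steps (full windows only).
The Sobel field is computed once per image and sliced per window, so
window borders use true image neighbors rather than per-patch padding.

## Scanpaths

Saccade statistics are binned empirical distributions (0.5° amplitude
bins, 10° direction bins); sampling draws a bin by mass and a uniform
value within it. Scanpaths chain independently sampled saccades from a
random start; landings outside the image are re-sampled up to 20 times
then clipped. Each fixation's patch (default 50 px, shifted to fit
inside the image) is classified with the feature criteria, and
transitions are tallied as iso-feature (colored→colored or
oriented→oriented), cross-feature (colored↔oriented) or other (any
transition touching an unclassified patch). Percentages are reported
over all transitions and, separately, over feature-labeled transitions
only, since the appropriate denominator is a genuine modeling choice.

## Eye events

Gaze speed is computed by central differences and smoothed with a 7-ms
boxcar; fixations are maximal runs below 100 deg/s, discarding runs
shorter than 50 ms. The smoothing and minimum duration suppress
jitter-induced splits and are configurable. Microsaccades are
within-fixation speed excursions above 3 s.d. of the within-fixation
mean while below the saccade threshold. Pseudo-trials pair consecutive
fixations: gray → test gives an unadapted trial, adapter → test an
adapted one; a trial is kept only when the population's aggregate
receptive-field box, translated by gaze, lies entirely inside one
quadrant and the monitor. An intervening fixation on any other region
breaks the pair (direct succession required). Covariate confound
checks compare fixation durations, pupil size and microsaccade
statistics across conditions with two-sided rank-sum tests.

## Tuning statistics

The color/orientation selectivity index of a tuning curve is the
normalized circular vector sum CSI = |Σ_i r_i e^{iφ_i}| / Σ_i r_i with
φ = θ for color and φ = 2θ for orientation; the preferred angle is the
argument of the sum (halved for orientation), and an all-zero curve is
reported as undefined rather than untuned. Significance uses the
Rayleigh test on the response-weighted circular distribution. Because
the spikes of one trial are not independent observations, the nominal
sample size is replaced by an effective one estimated from the data:

    n_eff = (Σ_j T_j)² / Σ_j var(T_j),

where T_j is the response total at angle j and var(T_j) comes from the
within-angle trial variance. This reduces to the total spike count for
Poisson-dispersed counts and keeps the test calibrated under over- or
under-dispersion (measured type-I error 0.04–0.05 at 1000 simulated
nulls); a fixed effective n and the count-capped variant remain
available. Neurons with peak tuning-curve rates below 10 spikes/s are
excluded from tuning classification.

Time-resolved tuning slides a 200-ms window in 5-ms steps over binned
counts, computing CSI and the Rayleigh p per window. The p-values of
one neuron's windows within one condition form the Holm-Bonferroni
family (statsmodels' step-down implementation, verified against a
brute-force oracle), and the tuning latency is the first window start
with a corrected significant test. Latency differences are recovered
to within one grid step when the response is sharp and the onset sits
well inside the window grid; near the epoch edge, or with borderline
per-window significance, the first-crossing estimator saturates or
blurs — an intrinsic property of the definition, visible in the tests.

## Population statistics

**Noise correlations.** Per stimulus, each neuron pair's Pearson
correlation over trials after excluding, per pair, trials where either
neuron's |z-scored rate| exceeds 3; pair values are averaged across
stimuli. Neurons with peak rates below 5 spikes/s are dropped; pairs
with fewer than 3 usable trials at every stimulus are reported
missing.

**Projected-PC variance ratio.** Neurons whose response variance
exceeds the across-neuron mean by more than 2 s.d. are removed; trial
counts are equalized by subsampling. PCs are fitted (SVD) to the
unadapted trials×neurons matrix; both conditions — each centered on
its own per-neuron means so the statistic reflects variance structure
rather than mean-rate shifts — are projected onto those axes, and the
per-axis ratio variance(unadapt)/variance(adapt) is averaged over the
leading PCs capturing 90% of the unadapted variance. The estimate and
its error are the mean and s.d. over 100 paired subsampled repeats
(80% of trials, one index set applied to both conditions, so identical
conditions give exactly 1). A one-sided Wilcoxon signed-rank across
the leading PCs tests ratio > 1. Two caveats: fitting and evaluating
the PCs on the same unadapted sample biases the null ratio upward by
O(neurons/trials) (≈0.05 at 320 trials × 15 neurons, <0.01 at 2400
trials) — comparisons across conditions of equal size are unaffected,
but absolute ratios at small trial counts inherit the bias; and with
fewer trials than neurons the PC count is trial-limited (warned, not
fatal).

**Decoding.** Two-class linear discriminant analysis on neighboring
stimuli (22.5° apart for color, 11.25° for orientation) with a
shrinkage-regularized pooled covariance (Ledoit-Wolf), since sessions
can have more neurons than trials per class. Stratified random 70/30
train/test splits are repeated 500 times; the mean test accuracy minus
the 50% chance level is reported. Note the iterations share one
dataset, so the across-iteration s.e.m. understates the protocol's
sampling noise; the dataset-level binomial s.e. is the right yardstick
for null comparisons. Passive-fixation sessions summarize decoding as
the mean over four evenly spaced neighboring pairs; free-viewing
sessions decode the two test stimuli using whole-fixation counts.

## Experiment drivers

`run_fixation` generates interleaved unadapted/adapted trials and
tabulates per-neuron selectivity, the fraction of initially untuned
neurons becoming tuned, mean selectivity/preferred-angle/rate changes,
optional tuning-latency shifts, noise correlations, the PC variance
ratio and decoding. `run_freeview` chains fixation detection,
pseudo-trial extraction (spike counts attached to detected fixations
by maximal temporal overlap with the generated episodes), covariate
checks, per-condition decoding and the PC ratio; sessions with fewer
than 10 trials per condition are marked underpowered, and decoding is
skipped when a condition lacks one of the test stimuli. `run_scenes`
generates patch-structured scenes, scores sliding-window feature maps,
simulates 300 saccades per image and tallies transition fractions. All
drivers are deterministic under their seeds, and every summary value
recomputes from the generated intermediates.

Problem sizes in the test suite are desk-scale by design: sessions of
30 neurons and ~450 trials/condition, 20-seed direction checks with
150 decoder iterations and 30 PCA repeats, and 160×160 surrogate
scenes; they exercise every code path at the paper's sampling
structure without cluster-scale runtimes.

## Known limitations

- Counts from integerized truncated-normal rates are approximately,
  not exactly, mean/variance-calibrated at very low rates (rounding
  adds ~1/12 count² variance; truncation biases means when rates
  approach 0).
- The scene generator's patches are internally homogeneous; classifier
  accuracy on natural images with mixed or weak features is untested
  by construction.
- The orientation gate of `classify_patch` (Rayleigh at one effective
  observation per pixel) is sensitive on large uniform-noise patches
  because discrete gradient kernels are anisotropic.
- The projected-PC ratio inherits the finite-sample fit bias described
  above; its per-session error bars come from subsampling, not from an
  unbiased estimator.
- Free-viewing spike counts are per-fixation aggregates; no
  within-fixation dynamics (e.g. response latency after fixation
  onset) are modeled.
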