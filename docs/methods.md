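# Methods

This note documents the models, parameter choices and numerical decisions
behind `afferent_csd`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Session model and conventions

A recording session holds per-ROI raw fluorescence and neuropil traces at
the volumetric frame rate (default 1.03 volumes/s), wheel position at
15.5 Hz, per-frame affine registration parameters and Z-plane shifts, and
a background-fluorescence movie binned into 40×40-pixel tiles over a
626×423 µm² field of view. Frame `k` is timestamped `k / frame_rate`;
image coordinates are µm from the top-left corner with `x` lateral and `y`
posterior, so "anterior" is −y (recorded in the container metadata). The
container is HDF5 with groups `/traces`, `/background`, `/behavior`,
`/registration`, `/meta`; dataset timestamps are disabled so identical
sessions produce byte-identical payloads.

## Signal chain

Neuropil-corrected fluorescence is `F = F_ROI − F_np + ⟨F_np⟩` (mean over
the whole recording, so the corrected trace keeps the raw ROI mean). The
baseline `F₀(t)` is the 10th percentile of the trailing 32-s window, with
linear interpolation between order statistics; before 32 s have elapsed
all available history is used rather than emitting undefined values.
`ΔF/F₀` is z-scored by subtracting the median of the full trace and
dividing by the standard deviation over quiet wakefulness, defined as the
stillness mask (no locomotion, ≥ 30 s from any bout). Events are maximal
runs with z strictly above 1 whose length is at least 1 s at the frame
rate and whose peak ΔF/F₀ reaches 0.05; no gap tolerance is applied.

Two deliberate readings: "consistently exceeded" is strict `>` with no gap
bridging, and the median in the z-score uses the full trace (the quiet
restriction applies to the SD only). Both are configurable.

## Locomotion

Velocity is the first difference of wheel position times the wheel rate,
block-averaged onto frame intervals. The binary locomotion state is the
Viterbi path of a two-state Gaussian HMM fit to speed (|velocity|) with 20
seeded EM restarts, keeping the best likelihood; the state with the higher
emission mean is "locomoting", which makes the labelling invariant to
state-index permutation. Bouts are locomoting runs sustained ≥ 2 s;
stillness excludes ±30 s around every bout. A constant velocity series is
degenerate and yields all-still with a warning.

## Deformation

The 2×2 linear part A of each frame's affine correction is decomposed via
its singular values s₁ ≥ s₂ (rotation invariant): isotropic stretch
`√(s₁s₂) − 1`, converted to µm through r_ref = half the FOV diagonal (the
displacement of a corner under the pure isotropic part), and shear
`(s₁ − s₂)/2` (dimensionless; also expressible as µm at r_ref). Singular
frames are flagged and interpolated from neighbours. Z-shift is the plane
correction times the plane spacing (default 5 µm), positive toward the
skull. The SVD split is the package's methodological choice for an
under-specified step; it is symmetric in expansion/compression and reduces
to the intuitive answer on diagonal matrices.

## Fiber clustering

ROIs belonging to one axon co-activate, so the pipeline correlates binary
event indicators restricted to quiet samples, thresholds the Pearson
matrix at 0.7 (ROIs with no quiet events get correlation 0 and are
flagged), and clusters the cosine dissimilarity between adjacency rows
with average linkage. The flat cut is at cophenetic distance 0.75: on the
[0, 1] range produced by binary non-negative rows, same-fiber ROIs sit
near 0 and unrelated ROIs near 1, so a mid-range cut separates fibers
while tolerating single-event discrepancies. (Any cutoff at the top of the
cosine range — e.g. 2 — is vacuous: all merges happen below it and every
ROI lands in one cluster; likewise a depth-2 inconsistency coefficient is
bounded by 2/√3 and can never exceed 2.) Every cluster is accepted;
there is no manual screening step. Fiber activity is the mean of the
member ROIs' z-traces.

## CSD wave

Within 5 min of the trigger, the FOV-mean trace F_FOV and its 1-s-smoothed
derivative define the initial period (derivative max → min); F_pre is the
10th percentile of the preceding 30 s; the wave onset/offset are the
outward crossings of 0.1·max(ΔF/F_pre) around the peak. The raw
frame-to-frame derivative at ~1 Hz is noise-dominated, hence the 1-s
moving-average smoothing.

Each background bin (bins contaminated by ROI pixels, within 8 px, are
excluded) is fit over −6…+14 s around the onset to a logistic
`A/(1+exp(−(t−t₀)/τ))+K`. Initialization is multi-start: t₀ on a 1-s grid
across the window × τ ∈ {0.5, 1, 2} s, the three best starts by SSE
refined by least squares. Fits with R² < 0.5, τ > 2 s or τ < 0 are
excluded. Speed is 1/slope of the regression of bin onset time on the
projection of bin centers onto the propagation axis, reported in mm/min.
Direction comes from the wavefront contour at the median onset time: the
onset map is interpolated by a least-squares plane, whose level line at
the median onset *is* the contour; the direction is its orthogonal unit
vector oriented toward increasing onset (identically the plane gradient).
Degenerate cases raise: near-zero onset variance ("no propagation",
simultaneous activation) and collinear bin centers (direction undefined).

Along-fiber pace applies the same logistic fit to each ROI of a long
(> 200 µm, ≥ 3 ROIs) fiber and regresses onset on arc-length distance;
the slope is the pace in s/mm (reported instead of speed because
locomotion-evoked activation is near-simultaneous and speed diverges).

## Ongoing activity

Ongoing activity is the fraction of stillness time inside events per 1-min
bin; bins with under 50% stillness coverage are missing. Baseline mean and
SD come from the ≥ 15 usable bins before the wave onset. A bin is elevated
above mean + 2 SD and reduced below mean − 2 SD; when that lower threshold
clips at zero — common, since sparse clustered events make the baseline SD
comparable to its mean — "reduced" degenerates to complete silence (zero
occupancy with a non-silent baseline). An afferent is activated
(suppressed) when a qualifying run lasts > 10 consecutive minutes and
starts within 30 min of the wave offset; latency is run start minus wave
offset, duration is the run span.

Run construction is where the statistical power lives. Missing bins never
break a run (they carry no evidence; capped at 10 consecutive), because
locomotion bouts with their ±30 s margins routinely blank 3–5 consecutive
bins and would otherwise truncate genuine 25-min changes. Up to 3
consecutive measured sub-criterion bins are bridged and a run must keep at
least 60% of its measured bins qualifying: with clustered events, a
genuinely elevated bin (30% occupancy against a ~21% threshold) qualifies
only ~3 times in 4, so an unbridged rule misses many true changes, while a
spurious majority-above-2SD run has probability ~10⁻⁵ per afferent. The
strict silence criterion bridges nothing: any measured non-zero bin ends
it. The ±2 SD bin rule itself is this package's operationalization of a
"sustained change" (the quantitative criterion is not fixed by the
source methods); k and all run parameters are configurable.

## Encoding models and sensitization

Each afferent's z-trace is modelled as a Gaussian GLM on five predictor
families — locomotion state, velocity, scale, shear, Z-shift — expanded
into one-frame shifts spanning −6…+6 s (13 delays per family at ~1 Hz; 65
columns). Positive delay means the predictor leads the response; rows with
undefined shifts are trimmed symmetrically. Columns are z-scored, and the
post-CSD design reuses the baseline-epoch statistics so coefficients
compare per physical unit of deformation across epochs — essential to the
"equal deformation, larger response" logic. Constant columns are dropped
and recorded.

The elastic-net mixing parameter is 0.01 (nearly ridge); the penalty
weight is selected by 10-fold cross-validation with contiguous folds
inside a contiguous first-75% training segment (both choices respect
temporal autocorrelation), minimum-CV-error rule, then refit on the full
training segment. Model quality is deviance explained on the held-out last
25%, with the intercept-only null fit on the training mean; well fit means
≥ 0.05. The post-CSD epoch starts 60 s after the wave offset so the acute
wave transient does not contaminate the fit. Family contributions refit
the model at the selected penalty without the family's columns
({locomotion state, velocity}, {scale, shear, Z-shift}, and each
deformation member singly); the drop in held-out deviance explained,
floored at 0, is the family's contribution.

Sensitization decision table: both epochs well fit → sensitized if any
family's peak |β| across delays rises ≥ 25% relative to
max(peak_pre, 0.1), desensitized if none rises and one falls by the same
margin, else unchanged; only post well fit → sensitized (unmasked); only
pre → desensitized (lost); neither → never fit. The 25% margin and 0.1
floor are set from the measured cross-epoch estimation noise of a family
peak (±15–25%): a smaller margin miscalls stable afferents, while a
genuine gain — e.g. a doubling — clears 25% by a wide margin.

## Synthetic sessions and ground truth

The generator emulates the statistical structure the analysis assumes.
Locomotion is a two-state Markov chain (bout entry 0.3/min, mean bout 8 s,
run speed 8 ± 1.5 units/s smoothed over ~1 s); wheel position integrates
the velocity at 15.5 Hz. Deformation series are causally filtered velocity
(exponential, τ = 1 s) with gains (0.4 µm, 0.0025, 0.5 µm per velocity
unit for scale, shear, Z-shift) plus substantial independent Gaussian
dynamics (1.0 µm, 0.006, 1.2 µm) — the axes are partially, not fully,
correlated, which matters both for realism and for coefficient
identifiability. The planted series are re-encoded exactly into affine
matrices (singular-value construction with a small random rotation) and
plane shifts, so the deformation module recovers them to machine
precision.

Afferent events are Poisson bursts: onsets at a calibrated rate, geometric
duration (mean 2 frames), amplitude 6 z-units ± 15%, convolved with a
peak-normalized difference-of-exponentials GCaMP6s kernel (0.2 s rise,
1.5 s decay — sensor-literature values; the source gives none). Bursts
rather than impulses are essential: single-frame transients leave so many
noise-flipped edge frames that within-fiber event-indicator correlations
fall below the 0.7 clustering threshold. The baseline rate is calibrated
so detected events occupy 6.9% of stillness time: a seeded Monte-Carlo
fixed point that pushes candidate rates through the actual analysis chain
(baseline, standardization, detection), initialized from an analytic
run-enumeration expectation. Purely analytic calibration misses two real
effects — the standardization scale includes the transients' own shot
noise, and the rolling-percentile baseline adds estimation noise — and
lands ~20% low.

The planted GLM drive (per-fiber coefficients on baseline-standardized
predictors; deformation-coupled fibers use β = 0.8 on Z-shift, 0.48 on
scale, 0.4 on locomotion state, delay 0) is added directly to the latent
z-trace, not convolved with the kernel: convolution would spread roughly
half the coefficient mass onto neighbouring delays and make exact recovery
impossible by construction. ROIs of a fiber share the fiber trace plus
independent unit noise; fluorescence is `F = F₀·(1 + 0.02·z)` with a
constant-plus-noise neuropil channel.

The CSD wave is planar: onset at each point is entry time plus projected
distance over speed (defaults 3.8 mm/min, bearing 90° = posterior), with a
logistic rise (τ = 1 s), 15-s plateau and 20-s exponential return, painted
into ROI traces (amplitude 25 z) and background bins (amplitude 60 on a
base of 100, optional noise as a fraction of amplitude). The ground-truth
wave onset/offset use the same 10%-of-peak crossing convention as the
detector, computed in closed form on the noiseless shape. The return
constant is chosen so per-ROI tails fall below the event threshold by the
wave offset; a slower return leaks spurious minutes into the
suppression-latency bookkeeping. Post-CSD effects: 10% of fibers
activated (occupancy 30% after a 25-min delay, 25-min duration), 20%
suppressed (silenced from the wave offset, 25 min), bout rate scaled by
0.6, deformation coefficients doubled in sensitized fibers, couplings
switched on (unmasked) or off (lost) in others.

## What the tests show — and what they do not

Every stage is tested by recovery of planted parameters plus brute-force
oracles (run enumeration for events and bouts, trailing-window percentiles,
SVD, BH step-up by hand, closed-form t statistics). Passing shows the
implementations compute what they claim under data that satisfies the
model's assumptions: planar single waves, logistic onsets, Gaussian noise,
linear lagged coupling, stationary baselines. Real recordings violate all
of these to some degree — curved or multiple wavefronts, bleaching,
Z-motion artifacts coupling into fluorescence, non-Poisson afferent
statistics, nonlinear indicator dynamics, drifting baselines — so recovery
here bounds correctness of the code, not performance on data. Two
quantitative caveats: the encoding-model coefficient recovery is
demonstrated at signal-to-noise ≥ 1 (at the full default event load, the
transients' shot noise caps SNR near 0.5 and the cross-validated penalty
shrinks peak coefficients by ~35%, an intrinsic ridge-bias/variance
trade-off, not a bug); and the ongoing-activity classifier's operating
point was set by the power analysis above, so its sensitivity claims are
specific to ~30% activated occupancy against a ~7% baseline.

## Sizes and determinism

Default test and acceptance runs use sessions of 25–120 min at 1.03
volumes/s with 8–12 fibers (problem sizes chosen to exercise every rule,
including the ≥ 15-baseline-bin and > 10-min-run constraints, with clear
statistical margins). Every stochastic component — generator, HMM
restarts, bootstrap, penalty selection — is driven by explicit seeds, and
repeated runs are bit-identical. The paired-test bootstrap is a seeded
2,000-resample percentile interval; an iterated (double) bootstrap is
deliberately out of scope.
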