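# Methods

## Data model

A burst is one duty-cycled recording interval of a collar-mounted tri-axial
accelerometer: `n` samples per axis (default 110) at `sampling_rate` Hz
(default 33.33), so 3.3 s of signal every 2 min. Axes follow the collar
convention x = sway, y = surge, z = heave. Acceleration stays in device
units throughout; every downstream predictor is scale-consistent, so
g-calibration would only rescale features uniformly. Ground truth is an
ethogram of six mutually exclusive classes (feeding, grooming, resting,
caching, trotting, walking) plus a rejection category "other" that is not a
trainable class.

Labelling joins observations to bursts by exact timestamp equality after
applying a user-supplied per-collar `clock_offset` (seconds). Collar clock
drift is corrected by a human comparing signal to notes; the package
deliberately exposes only the resulting fixed offset rather than automating
that judgement. Observations listing more than one behaviour mark mixed
bursts and are excluded before training. All drops and exclusions go to a
structured JSON-lines run log.

## Predictors

Per axis: mean, sd, inverse coefficient of variation (mean/sd), variance,
skewness, kurtosis. Moment conventions are *population* (divide by n)
variance/sd, and standardized 3rd/4th central moments with kurtosis in
Pearson form (normal → 3), not excess. These conventions are fixed here for
reproducibility; alternatives (sample moments, excess kurtosis) differ by
monotone transforms that tree and network classifiers absorb.

Degenerate windows (sd = 0 on an axis) map inv_cv, skewness and kurtosis to
the sentinel 0, keeping feature vectors finite on perfectly still windows.
Skewness/kurtosis are computed from standardized residuals (d/sd) rather
than ratios of raw central moments, which would underflow for near-constant
windows.

Cross-axis: q = mean per-sample vector magnitude; pitch =
atan2(ȳ, √(x̄²+z̄²)) and roll = atan2(x̄, √(ȳ²+z̄²)) in degrees (static
component = window mean; an all-zero mean vector is an error since
orientation is undefined); ODBA = Σ over axes of mean|a − ā|, with the
static component again the window mean — on windows ≤ 3.3 s there is no
room for a running-mean smoother, and the window mean is the only static
estimate defined at this scale. Published pitch/roll conventions vary in
sign and axis assignment; any consistent choice differs from another by a
sign/offset the classifiers absorb, so one is fixed rather than exposed.

Spectral: the whole one-sided unnormalized FFT magnitude spectrum of each
axis, DC included, no taper — floor(w/2)+1 bins per axis. Total: 18 + 4 +
3·(w//2+1) predictors (142 at w = 79). The column order is frozen
(`features.feature_names`) and versioned so persisted models and feature
tables stay portable.

## Moving window and splitting

`WindowPlan(w, step=1)` extracts all offsets 0, step, … ; with step 1 a
length-n burst yields n − w + 1 windows (32 for 110/79). The step is
parameterized for sensitivity studies but the procedure itself uses 1.

Train/test splitting is stratified per class at *burst* level, before any
windowing, because windows of one burst are near-duplicates and would leak
across a window-level split. Per-class train counts round half-up from
`train_frac · count` with at least one burst forced into each partition.

## Classifiers, rejection and voting

Back-ends: radial-kernel SVM (pairwise-coupling probabilities), random
forest with 500 trees (tree-vote fractions), and a feed-forward network —
input, one hidden rectifier layer of width max(64, 2·classes), softmax
output; i.e. a three-layer architecture counting input and output layers —
trained by Adam with a fixed epoch budget and seed. Features are z-scored
(fit on the training split only) for svm/ann; the forest is scale-invariant
and receives raw features. Class imbalance is *not* reweighted by default —
the captive class frequencies are themselves informative — but
`class_weight` is exposed.

A window's class is accepted only if its maximum probability strictly
exceeds τ; otherwise "other". τ defaults to 0.7 for the network and to
None (no rejection) for svm/rf, where the thresholding idea is not part of
their standard usage here. The burst class is the strict absolute majority
of its window classes; without one, the burst is rejected as "other" — the
conservative fallback consistent with the threshold's purpose (the
alternative, plurality, would assert a class on evidence the threshold was
designed to doubt).

## Window-size selection

Each candidate w is scored on the same burst-level split by
mean(mean recall, mean precision, 1 − proportion "other") computed at
window level. Accuracy is computed but excluded from the score: with one
dominant class, true negatives inflate accuracy for every other class.

The raw curve is smoothed by a penalized cubic B-spline (P-spline:
basis dimension 40, second-order difference penalty on coefficients,
smoothing parameter minimizing GCV over a log-spaced grid spanning 1e-8 to
1e6). Slopes are successive difference quotients of the fitted values.
Chosen is the smallest size whose fitted score lies within
`slope_tol · range` of the fitted maximum *and* whose slope magnitude is at
most `slope_tol` (default 1e-3 on the score scale, which is already in
[0, 1]); if no size qualifies — e.g. a strictly rising curve — the argmax
is chosen. The smallest-window preference reflects that smaller windows
produce more augmented samples at equal performance. On a noiseless
parabolic curve the spline reproduces the curve to ~1e-9 and the rule
returns the analytic peak; on a flat curve it returns the smallest size.
Note that with cleanly separable training data the score saturates near 1
for all sizes, and the plateau rule then legitimately selects the smallest
candidate — the selection machinery only discriminates when performance
actually varies with window size.

## Field validation

GPS clusters: single-pass segmentation; a fix extends the current cluster
iff it lies within 50 m (haversine, sphere R = 6371.0088 km) of the
cluster's *first* fix, else it anchors a new cluster. Predictions map to
the cluster whose time span (anchor to last member, half-open on the right)
contains the burst start; the alternative — interpolating a position per
burst — needs assumptions about movement between fixes that the temporal
rule avoids. Clusters with fewer than `min_items` (10) assigned bursts
contribute nothing, so singleton clusters on a travelling track never count
as "clustered". Lowering `min_items` can only add qualifying clusters,
hence in-cluster proportions are monotone in it.

Speed: per-interval haversine distance over elapsed time between
consecutive fixes; a burst within `max_dt` = 10 s (boundary inclusive) of
its nearest fix inherits the speed of the interval ending at that fix (the
first fix uses the interval starting there). The resting-vs-trotting
contrast uses the classical two-sample Wilcoxon rank-sum with normal
approximation and tie correction, one-sided (resting slower).

Diel composition counts assignments per month × time-of-day bin (default
30 min, UTC); months with under 15 covered days are flagged as
uninterpretable. Actograms average a value (ODBA, or a 0/1 behaviour
indicator) into a day × bin grid, leaving gap days as blank rows;
sunrise/sunset come from the standard NOAA solar-position approximation
(minutes-level accuracy, ample for drawing day/night boundaries).

## Synthetic data

The generator emulates the *structure* of a captive-training / wild-transfer
study, not fox biomechanics. Per class, each axis is orientation +
amplitude-jittered sinusoid (random phase) + Gaussian noise: resting is
aperiodic and quiet (noise sd 0.03 in device units ≈ g); walking 1.5 Hz,
amplitude 0.25; trotting 3 Hz, amplitude 0.7 — gait-like frequencies within
the 16.7 Hz Nyquist of the 33.33 Hz sampling; grooming is broadband
noise-dominated (sd 0.30); feeding (0.8 Hz, 0.15) and caching (2.2 Hz,
0.35) are intermediate, with distinct static orientations throughout. The
defaults were chosen once so that moment and spectral predictors separate
the six classes; every parameter is overridable to study confusion.

The default captive dataset reproduces the natural class imbalance
(feeding 367, grooming 1140, resting 2114, caching 197, trotting 179,
walking 162; 4159 bursts), which is deliberately not reweighted in
training.

The wild scenario runs 7 days from the March equinox at Berlin's
coordinates: a burst slot every 120 s, GPS every 240 s. The behaviour state
persists with probability 0.93 per slot (mean bout ≈ 28 min; a simple
stickiness parameter rather than a semi-Markov model — sufficient to create
rest dwells and travel legs), else it is redrawn from an hour-of-day
schedule that rests by day and travels by night. Stationary states jitter
within a 10 m dwell radius of the bout anchor; walking and trotting move at
1 and 3 m/s along a slowly-turning heading. This yields the four
validation signatures by construction: night-dominated trotting, resting
confined to < 50 m dwells (GPS clusters), resting speeds near 0 vs
trotting near 3 m/s, and nocturnal high-ODBA actograms.

**What passing means.** The synthetic classes are cleanly separable, so the
network recovers wild truth at kappa ≈ 1 and the captive validation
saturates. That demonstrates the *pipeline* — augmentation, thresholding,
voting, and the validation machinery — is wired correctly end to end, not
that real field data would classify this well: real signals carry
collar-fit variability, individual gait differences, behaviours outside the
ethogram, and mixed bursts at much higher rates. The rejection threshold
and the "other" accounting exist precisely for those harder cases, and the
`mixed_burst` splicer plus the overridable signal model let users study
them.

## Numerical and degenerate-input choices

* Strict inequalities at both rejection points (probability > τ; vote
  count > 50 %); ties reject.
* Probability rows are validated to sum to 1 within 1e-6.
* Undefined one-vs-rest ratios (class absent from truth or predictions)
  report 0 and set an `undefined` flag rather than NaN.
* Kappa's chance term defaults to the standard truth-marginal × predicted-
  marginal product (equivalent to the classical two-rater definition, and
  to computing kappa directly from the label pairs); a variant using TP+TN
  in place of the truth marginal is available behind `chance="printed"`.
  With an "other" column present, rejected predictions lower observed
  agreement and enter no chance product, which penalizes — rather than
  hides — heavy rejection.
* Empty confusion matrices, windows shorter than 2 samples, windows larger
  than their burst, single-class training, duplicate GPS timestamps and
  empty vote sequences all raise typed errors from `burstclass.errors`.

## Problem sizes used in the checks

The test suite trains on 20-burst-per-class captive sets for speed and runs
one full-scale experiment (4159 captive bursts → 133 088 windows of 142
predictors; 7-day wild track, 5040 bursts, 2520 fixes) with a 30-epoch
network budget — performance saturates well before that on these data. The
acceptance script additionally sweeps window sizes 20–110 in steps of 10 on
a 90-burst subset with a 15-epoch budget.

## Known limitations

* The signal model has no collar slip, no terrain, no individual
  variation, and no behaviours outside the ethogram; transfer failure
  modes (e.g. a model collapsing to one class on wild data) can be induced
  only by deliberately distorting the signal model.
* Exact-timestamp label matching assumes drift has been corrected upstream;
  there is no fuzzy matching window.
* Cluster membership for bursts is temporal; no position interpolation.
* The smoother's GCV grid search assumes a single smoothing parameter;
  heteroscedastic score curves are smoothed as if homoscedastic.
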