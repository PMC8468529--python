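# Methods

## Problem and data model

The package classifies each second of a dairy cow's day as lying or
non-lying from a collar-mounted BNO055 inertial unit at the lower neck.
The sensor runs in NDOF fusion mode: it reports gravity-removed linear
acceleration (m/s², three axes) and an absolute orientation as Euler
angles (heading ∈ [0, 360), roll ∈ [−90, 90], pitch ∈ [−180, 180],
degrees) at a nominal 10 Hz. Ground truth is a per-second rasterization of
video-coded ethogram intervals: exclusive states (lying, lying_down,
standing_up, standing, walking, grazing, feeding, idle) plus overlay
activities (chewing, ruminating, drinking, other) that may co-occur with
an exclusive state.

Timestamps are integer milliseconds UTC; label intervals are half-open
`[start, end)` seconds. A second takes the behavior of the interval
covering its **midpoint** — the source protocol never states how
sub-second boundaries were resolved against the 10 Hz stream, so the
midpoint rule is this package's convention (deterministic and unbiased at
boundaries). Inter-sample spacings beyond ±20% of the nominal period are
treated as declared gaps (too-long) or rejected (too-short); streams are
assumed pre-synchronized (the field hardware used GPS/RTC clocks).

## Segmentation

Windows of `window_s` seconds (default 5, supported 1–20) advance by a
stride expressed as a fraction of the window (default 1.0 = disjoint). The
k-th window in a gap-free run starts `floor(k · w · f)` samples in
(`w` = samples per window, `f` = stride fraction); the fractional
accumulator reproduces the count `floor((N − w)/(w·f)) + 1` for every
stride, including non-integer steps such as 12.5 samples at 25% stride.
Windowing restarts after every data gap, and windows truncated by a gap or
the stream end are never emitted. Whether the original pipeline restarted
windows after gaps is unstated; restarting avoids mixing discontinuous
samples.

Training uses only **pure** windows — every covered second valid, a single
exclusive behavior, empty overlay set (a strict, 100%-purity reading).
For the binary task, lying → `lying` and grazing/walking/standing/feeding
→ `non_lying`; the transition events lying_down/standing_up never yield
training windows and count as non-lying in evaluation timelines, because a
lying bout is defined as the time strictly between a lying-down and a
standing-up event.

## Feature sets

- **OD24** (orientation-dependent): max, mean, median, population σ of
  the six raw axes (ax, ay, az, heading, roll, pitch), in that order.
- **OI36** (orientation-independent): 18 functions on the per-sample
  Euclidean magnitudes of the acceleration and Euler (NDOF) vectors.

The source names the 18 functions but defines none of them; every
numerical convention below is this package's and is pinned by oracle
tests:

- σ uses divisor *n*; kurtosis is excess (Fisher) and skewness
  Fisher–Pearson, both defined as 0 for zero-variance series;
- IQR = Q3 − Q1 with linear-interpolation quantiles; RMS = √mean(x²);
- mean crossing rate = (# consecutive pairs of mean-centered samples with
  strictly opposite signs) / (n − 1); zeros break no crossing;
- spectrum: real DFT of the mean-removed window, no taper, no padding;
  one-sided power `p_k = |X_k|²/n` for `k = 1..⌊n/2⌋` (DC excluded).
  Under this normalization Σp_k equals `n·var/2` for odd *n* (plus half
  the Nyquist term for even *n*) — the Parseval oracle test pins the
  constant. Spectral energy = Σp_k; peak frequency = `k*·rate/n` Hz with
  ties to the lowest bin and 0 for an empty spectrum; frequency-domain
  entropy = −Σ q_k ln q_k of the normalized power (0 if energy is 0);
- the "first five frequency-profile components" are read literally as the
  magnitudes of the first five non-DC DFT coefficients normalized by √n,
  i.e. `√p_k` for k = 1..5, zero-padded when the window has fewer than
  five non-DC bins. This phrase is genuinely ambiguous in the source; the
  interpretation is fixed here and stated prominently rather than guessed
  silently.
- The NDOF magnitude is computed on raw Euler degrees without unwrapping;
  heading wrap-around noise near 0/360 is accepted.

A rotation of the accelerometer frame preserves ‖a‖ exactly, so the
acceleration half of OI36 is bit-for-bit rotation-invariant; OD24 is not
(both facts are witness-tested). Feature order is stable and column names
(`acc_mag__rms`, `ndof_mag__peak_freq_hz`, …) are part of the persisted
model contract.

## Classifiers

Fixed hyperparameters (originally tuned by exhaustive grid search, not
re-run here): random forest — 95 trees, Gini, max depth 25, min split 2,
min leaf 1, 6 features considered per split, bootstrap sampling (the
source omits the bootstrap flag; sampling is the common default and noted
as unverifiable); decision tree — Gini, max depth 5; SVM — RBF kernel,
C = 10, gamma = "scale" (1/(n_features·var)); Gaussian naive Bayes. All
estimators are seeded; the seed is a required config field (default 42).

10-fold cross-validation is stratified (the source does not say; stratified
folds are the stabler default). Subject cross-validation trains only on
the designated animals and audits that test animals contribute no
training windows. Per-window binary labels are expanded to seconds; with
overlapping strides a second takes the majority label, ties going to
non-lying (a conservative tie-break for the positive class).

## Interbout filter

Runs of lying or non-lying shorter than 60 s are absorbed into the
behavior preceding them. The source states only the "preceding" rule;
cascades and the leading run are undefined, so the procedure is pinned:
within each valid segment, repeatedly relabel the leftmost short run that
has a predecessor and re-coalesce; only at that fixpoint may a short
*leading* run take the label of the run following it; repeat to global
fixpoint. The result is idempotent, never bridges invalid (unobserved)
seconds, and leaves every run ≥ 60 s except when a whole valid segment is
shorter than the criterion. The alternative 33-s criterion discussed in
the literature is deliberately not offered as a default.

## Bout matching and boundaries

Same-label bouts are matched by ≥ 1 s of temporal overlap (the source
requires only that "an overlap occurred"): 1:1 overlaps are *detected*;
one prediction spanning several ground-truth bouts marks them *merged*;
several predictions splitting one ground-truth bout mark it *divided*;
non-overlapped bouts are *missed* (ground truth) or *added* (prediction).
Many-to-many components resolve merged-dominant, which keeps the
categories disjoint and deterministic. Every ground-truth bout lands in
exactly one category (conservation is property-tested). Boundary
deviations (signed seconds, positive = model late; summarized as medians
and shares within ±4 s and ±10 min) and duration comparisons use only 1:1
detected pairs whose bouts are completely observed.

## Metrics

Lying is the positive class: TP = lying predicted lying, FN = lying
predicted non-lying, FP = non-lying predicted lying, TN = non-lying
predicted non-lying. (The source's prose swaps FP/FN relative to its own
equations and its reported numbers; the standard orientation above is the
only one consistent with both, and is used throughout.) Ratios with zero
denominators are reported as not-available, never 0. Percentages print at
one decimal, rounding half away from zero. `reconstruct_counts` inverts
published aggregate bookkeeping — total compared hours, ground-truth lying
share, FP/FN hours — into the full confusion matrix, which is how the
field study's headline metrics are reproduced without its (undeposited)
raw data.

Daily lying time splits at 06:00/18:00 local; animal-days with more than
10% of seconds unobserved are flagged excluded.

## Synthetic cow-days

The simulator generates the study's *conditions*, not its data. Bout
sequences are an alternating semi-Markov chain over grazing, lying,
walking, standing with log-normal bout durations (median × dispersion
σ_log = 0.5). The long-run time mix targets the observed training
distribution — grazing 51.0%, lying 32.2%, walking 7.6%, standing 9.2% —
and the lying-bout median is 57.7 min as reported on pasture; remaining
medians (grazing 25 min, standing 8 min, walking 3 min) are plausible
choices. Because the chain never self-transitions, entry weights `w` are
solved from `w_b(1 − w_b) ∝ mix_b / mean_duration_b` (fixed-point
`w ∝ r/(1 − w)`), which makes the embedded chain's stationary visit rates
times mean durations equal the target mix; residual finite-horizon bias is
about 2 percentage points over 30 simulated days. Lying bouts are flanked
by 5-s lying-down/standing-up events; ruminating overlays a random
sub-interval of half the lying/standing bouts.

Signals follow the NDOF split: posture lives in the Euler angles (per-bout
mean + AR(1) jitter; lying rolls the collar to ≈55°, grazing pitches the
head down to ≈−60°), motion in the acceleration (sinusoid on a random
direction + white noise; lying ≈ still at 0.02 m/s², standing small
weight-shift movement at 0.3 m/s²/0.4 Hz, walking 1.5 m/s²/1.8 Hz gait,
grazing 0.8 m/s²/0.8 Hz sweeps, ruminating adds 0.15 m/s² at 1.1 Hz).
All of these amplitudes are invented — the source publishes no
per-behavior signal statistics — and were chosen once on physical
plausibility. Collar-orientation shifts between farms are modeled as a
rotation about the neck axis applied to the acceleration plus the same
offset on roll (wrapped into [−90, 90)).

**What passing synthetic tests shows and does not show.** The default
signatures separate lying from non-lying essentially perfectly, so
held-out synthetic accuracies near 100% validate the pipeline's plumbing
(windowing, features, expansion, filtering, evaluation) and the *relative*
claim that the orientation-independent set survives collar rotation while
the orientation-dependent set does not. They say nothing about absolute
accuracy on real cows, where ruminating-while-standing is genuinely
confusable with lying; synthetic separability is a free parameter.

## Problem sizes and numerical choices

The test suite and the acceptance script run the synthetic experiments at
3-hour cow-days with 3 training and 2–3 held-out animals, 10 seeds for the
rotation comparison (paired sign test, ties discarded) — sizes chosen so
the full suite completes in well under a minute of simulation per
experiment while leaving dozens of bouts per condition. Windows too short
for five spectral bins zero-pad the frequency profile; zero-variance
windows produce all-zero dispersion/spectral features rather than NaN; no
feature value is ever NaN by contract.

## Known limitations

- The Euler-magnitude features inherit heading wrap-around and are only
  partially informative when heading dominates the norm; this mirrors the
  literal "NDOF vector magnitude" definition.
- The interbout filter's leading-run and cascade rules, the 1-s overlap
  threshold, the merged-dominant tie-break and the midpoint rasterization
  rule are package conventions where the source is silent; all are pinned
  by tests.
- Drift correction, video workflows, GPS, generalized additive day-effect
  models and inferential statistics (Wilcoxon, Kendall, ANOVA) are out of
  scope; standard packages fit them directly from this package's outputs.
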