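# Methods

This note documents the models, conventions, and design choices behind
`actigwas`, in the order data flows through the package.

## Measurement model and preprocessing

The target instrument is a wrist-worn triaxial accelerometer sampling at a
nominal 100 Hz with a ±8 g dynamic range.  The recorded signal is modelled
as

    a_measured(t) = G · (g(t) + d(t)) + b,     clipped to ±8 g,

where `g(t)` is the gravity component (unit Euclidean norm), `d(t)` the
dynamic (movement) acceleration, `G = diag(gain)` and `b` the per-axis
sensor miscalibration.

**Autocalibration.**  During stationary periods `d(t) ≈ 0`, so the measured
vector should lie on the unit-gravity sphere.  Stationary 10-s windows are
those whose three axis standard deviations are all below 13 mg — the
standard threshold in the UK Biobank accelerometer processing convention;
the window length is our choice, exposed in configuration.  Per-axis gain
and offset are estimated by iterated least squares: each stationary mean
vector is projected onto the unit sphere and each axis regressed onto its
target coordinate, composing the per-axis linear maps across iterations
until the mean absolute norm residual stabilises.  Gain and offset are
jointly unidentifiable unless the stationary orientations cover the sphere,
so calibration additionally requires stationary means beyond ±0.3 g on
every axis (the usual sphere criterion in wearable pipelines).  Calibration
*fails* — data pass through unchanged and the participant is flagged — when
there are fewer than 10 usable windows, coverage is inadequate, or the
final residual exceeds 10 mg.  The failure thresholds are design choices
(the source pipelines do not publish one); both are configurable.

**Resampling** is linear interpolation onto a uniform grid.  Recording gaps
longer than 1 s are left as missing (NaN) rather than bridged.

**Epoching.**  Non-overlapping half-open 30-s epochs anchored at the
recording start; a trailing partial epoch is dropped, so the epoch count is
`floor(duration / 30 s)`.  Per epoch we compute ENMO — the Euclidean norm
of the calibrated signal minus 1 g, truncated below at zero, averaged over
the epoch and reported in mg — plus per-axis SDs and the fraction of
samples at the clip limit.  ENMO truncation is the "removal of noise and
gravity" convention of the UK Biobank accelerometer working group; it is
non-negative by construction and invariant to rigid rotation of the device
frame.

## Feature extraction

Each 30-s window is reduced to a fixed 126-dimensional vector.  The
original feature list used for training on free-living reference data is
not enumerated in the public record, so the composition here is a design
decision honouring the hard constraints that downstream code relies on:
exactly 126 values, deterministic, a mixture of time- and frequency-domain
statistics, and finite on every valid input.  The vector comprises per-axis
and ENMO moments/quantiles (mean, SD, range, min, max, quartiles, skewness,
kurtosis, median absolute deviation), inter-axis correlations, roll/pitch
orientation statistics, signal energy and zero-crossing rates, and spectral
statistics from a Hann-tapered FFT of the full window (dominant frequencies
and powers, spectral entropy, power in eight fixed bands between 0.1 and
10 Hz, and ENMO autocorrelation at lags 0.1–2.0 s).  Degenerate inputs use
explicit conventions: correlations involving a constant axis are 0, and
skewness/kurtosis at zero variance are 0.  Features are not normalised —
the downstream classifier is tree-based and invariant to monotone scaling.

## Classification and smoothing

**Balanced random forest.**  Free-living behaviour data are heavily
imbalanced (sleep and sedentary dominate), so each tree is grown on a
class-balanced bootstrap: `min_class_count` draws with replacement from
every class.  Out-of-bag votes give an unbiased confusion matrix.
Prediction returns tree-vote fractions as class probabilities.

**Confusion-matrix HMM.**  The forest treats epochs as exchangeable;
isolated misclassifications ("blips") inside long behavioural bouts are
corrected by a hidden Markov model whose hidden states are the *true*
behaviours: the prior is the empirical true-state frequency, the transition
matrix comes from adjacent true-label pairs in training data, and the
emission matrix is the training confusion P(predicted | true).  This
emission direction is the only reading under which a confusion matrix
yields a proper HMM.  All counts receive an additive ε = 1e-4 before row
normalisation so no unseen transition or confusion produces a −∞ log path.
Decoding is Viterbi (maximum a-posteriori path) in log space, with ties
broken toward the earlier-indexed state; a forward–backward posterior-mode
decoder is provided as an alternative.  Note that distinct paths can attain
exactly the same posterior probability, in which case any maximiser is a
correct decode.

Agreement is scored with Cohen's kappa, `(p_o − p_e)/(1 − p_e)` with
chance agreement from the product of marginals; two identical constant
sequences (p_e = 1) are defined to have κ = 1.

## Non-wear, imputation, and participant QC

An epoch is *stationary* when all three axis SDs are below 13 mg; any
maximal stationary run of at least 60 min (120 epochs) is flagged
non-wear.  Non-wear epochs are imputed with the mean of worn epochs at the
same clock slot (one of 2880 30-s slots per day) on *other* days, applied
to ENMO and to each behaviour probability, with the label re-derived as the
argmax of the imputed probabilities; slots with no worn donor remain
missing.  This preserves the per-slot means of worn data.  Clock slots use
the device's local time as recorded, without daylight-saving adjustment.

Participants are excluded when: calibration failed; the recording-wide
clipped fraction exceeds 1% (the published rule names "too many clipped
values" without a number — 1% is our configurable choice); mean ENMO
exceeds 100 mg (implausibly high); or wear time is insufficient, defined as
less than 72 h of *worn* epochs or any of the 24 one-hour clock bins never
covered by a worn epoch.  Imputed epochs do not count toward wear time —
whether they should is ambiguous; counting only worn epochs is the stricter
reading and is flagged here as a documented choice.

## Phenotypes

Behaviour fractions are epoch counts for a class divided by all classified
epochs; hours/day is 24 × fraction, and sleep duration for genetic analysis
is the fraction-based quantity (whether the original derivation averaged
valid days instead is not stated; fraction × 24 is our choice).  Overall
activity is mean ENMO over worn + imputed epochs.  Short/long-sleep flags
mark the bottom/top cohort quintile with inclusive comparisons
(≤ 20th / ≥ 80th percentile, linear-interpolation percentiles); if all
values are tied, everyone carries both flags — degenerate but explicit.
Hypertension is SBP > 140 mmHg or DBP > 90 mmHg (strict, on raw pressures)
or blood-pressure medication use; for continuous analyses medicated
participants get +15/+10 mmHg added to systolic/diastolic pressure.

## GWAS summary-statistic post-processing

* **Variant QC** removes MAF < 0.1% and imputation info < 0.3 (boundary
  values retained).
* **HWE** uses the exact conditional test: conditioning on allele counts,
  the p-value sums the probabilities of all heterozygote counts (same
  parity as observed) no more probable than the observed one.  A chi-square
  mode exists for large counts.
* **Locus definition** is greedy distance clumping at p < 5e-9 with a
  ±400 kb window: repeatedly take the smallest-p remaining variant, open a
  locus, and remove everything within the window (boundary inclusive, so
  retained indices are separated by strictly more than 400 kb).  Ties in p
  break by position.  Novelty: an index is novel iff no previously reported
  variant on the same chromosome lies within ±400 kb.
* **Instrument selection** is greedy by ascending p at p < 5e-6, accepting
  a candidate iff its LD r² with every accepted instrument is < 0.001 and
  it is strictly more than 10,000 kb from each on the same chromosome.
  Both greedy procedures equal the exhaustive-search optimum (the maximal
  admissible subset with lexicographically smallest sorted p-vector); the
  test suite verifies this on random panels.
* **Replication sample size** inverts the non-central chi-square power
  function: the 1-df association statistic has non-centrality
  `n·r²/(1−r²)`, and `n` is chosen so the tail beyond the α critical value
  equals the requested power.  The normal-quantile closed form
  `(z_{1−α/2} + z_{power})²` agrees within 1%.
* **Sex-dimorphism z-test.**  The defining equation as printed divides the
  heritability difference by `sqrt(var_f − var_m)` — a *difference* of
  variances, which is undefined when var_f ≤ var_m.  The default mode
  implements exactly that and raises an explicit error on a non-positive
  radicand rather than silently "fixing" the formula; a `sum` mode provides
  the conventional variance of a difference of independent estimates.

## Two-sample Mendelian randomisation

All estimators operate on per-SNP exposure/outcome betas and SEs aligned to
a shared effect allele (palindromic SNPs with allele frequency in
0.42–0.58 are dropped during harmonisation as strand-ambiguous).

The primary estimator is **maximum likelihood**: a joint-normal model with
per-SNP true exposure effects as nuisance parameters and a single causal
slope θ.  For fixed θ the nuisance effects have a closed-form profile
optimum, leaving a one-dimensional profile likelihood maximised by bounded
scalar search; the SE comes from the numerical observed information.
**IVW** is the fixed-effect inverse-variance-weighted regression through
the origin (algebraically, the 1/SE²-weighted mean of per-SNP Wald ratios).
**MR-Egger** adds a free intercept after orienting exposure effects
positive; the intercept and its p-value diagnose directional pleiotropy,
and SEs carry a multiplicative over-dispersion factor floored at 1.
**Weighted median** interpolates the inverse-variance-weighted median of
Wald ratios; **weighted mode** takes the argmax of a Gaussian-kernel
density of the ratios with a modified Silverman bandwidth
(`0.9·min(sd, IQR/1.349)·n^{−1/5}`, multiplier configurable).  Median and
mode SEs come from a seeded parametric bootstrap of the ratios.  With one
instrument, every defined method reduces to the Wald ratio; Egger, median
and mode require at least three.

Sensitivity analyses: **Steiger** directionality compares the summed
variance explained in exposure vs outcome (per-SNP r² = 2·EAF·(1−EAF)·β²
for standardised traits) through a Fisher-z test; **leave-one-out** flags
instruments whose omission moves the estimate by more than one full-sample
SE; **bi-directional** testing reports both causal directions and a joint
verdict.

A known property worth stating: estimators that ignore exposure-side
sampling error (IVW, and to a lesser degree the profile ML) show mild 2-SE
undercoverage (~92–94% rather than 95.4%) at realistic instrument strength
in our simulations.  The acceptance thresholds account for this.

## Synthetic data

The generators exist so every stage is testable with known truth.

* **Accelerometer traces.**  Behaviour follows a semi-Markov chain over
  {sleep, sedentary, walking, moderate} with geometric dwell times and a
  uniform choice among the other states on exit.  Under uniform switching
  the long-run time share of a state is its dwell mean over the sum, so the
  default means (150/210/30/20 min) encode ~8.8 h/day sleep, ~12.3 h
  sedentary, ~1.8 h walking and ~1.2 h moderate activity, with an implied
  mean ENMO near 27 mg — plausible free-living wrist numbers.  Sleep
  arrives in multi-hour bouts without circadian placement (the machinery
  under test is indifferent to clock position of behaviours).  Per state: sleep/sedentary have near-zero dynamic
  amplitude (3/8 mg) with occasional movement bursts (posture shifts,
  probability 0.55/0.75 per epoch) — without these, genuine sleep would be
  indistinguishable from the 60-min non-wear rule, which real wrists avoid
  by moving every few minutes; walking is a 2 Hz sinusoid along a random
  movement axis (120 mg) giving the frequency-domain features a
  discriminative target; moderate is higher-amplitude broadband noise
  (250 mg).  Gravity has unit norm and a fresh random orientation each
  behaviour episode.  Gain/offset error and ±8 g clipping are injected
  last.  Non-wear blocks freeze the orientation and zero the movement.
* **Epoch-level series** emit the same state process directly as 30-s ENMO
  and axis-SD summaries, making multi-day QC and smoothing experiments
  cheap.  What these generators do *not* emulate: realistic gait harmonics,
  temperature drift, device firmware quirks, or the true joint distribution
  of free-living behaviours — so passing tests demonstrate the machinery is
  correct on its stated model, not that classifier accuracy transfers to
  real cohorts.
* **GWAS summary statistics.**  Variants sit on a single chromosome at
  fixed spacing in LD blocks of configurable size with block-constant
  correlation r = 0.8 (sufficient for clumping and pruning logic; not a
  recombination map).  Causal effects are Gaussian; non-causal variants in
  a causal block carry r-scaled signal; estimation noise has SD
  `1/sqrt(2·EAF·(1−EAF)·n)` and is r-correlated within blocks; p-values are
  two-sided Wald.  Marginal p-values are uniform under the null.
* **MR studies.**  Instruments are coded to the exposure-increasing allele
  (the standard harmonised orientation — necessary for "directional"
  pleiotropy to be directional), with true exposure effects bounded away
  from zero (≥ 4 SE at the default n = 100k, median F ≈ 50) and outcome
  effects `θ·βx + α_j + noise`.

All generators are seed-deterministic: identical inputs give bit-identical
outputs.

## Problem sizes and numerical choices

Tests use deliberately economical sizes chosen to make each check sharp
rather than large: calibration uses 4-h traces at 25 Hz with short dwell
times (many postures → good sphere coverage); smoothing-benefit experiments
use 50 single-day epoch-level replicates with a 76%-accurate synthetic
classifier; Viterbi is verified against exhaustive enumeration on 1000
random instances of up to 8 epochs; selection procedures against exhaustive
subset search on panels of up to 15 variants; the HWE exact test against
factorial enumeration for every table with N ≤ 20; MR recovery on 500
replicates of 50 instruments.  Optimisation tolerances: calibration
iterates to residual stability 1e-10 (max 500 iterations); the ML profile
search uses a bounded interval of ±10·(|IVW|+1) around the IVW start with
xatol 1e-10.

## Known limitations

* The 126-feature composition is this package's own (contract-compatible)
  design; numeric feature values are not comparable to any external
  implementation.
* Viterbi tie-breaking (earlier-indexed state) makes decodes deterministic
  but is one of several defensible conventions when distinct paths tie.
* The wear-time rule counts only worn epochs; cohorts processed with the
  alternative (imputed epochs count) reading would admit slightly more
  participants.
* Bootstrap SEs for weighted median/mode depend (weakly) on the bootstrap
  seed and replicate count; both are exposed as arguments.
* No multivariable MR; single-exposure analyses only.
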