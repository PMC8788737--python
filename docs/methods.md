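# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `era3d`.  It is written for a reader who wants to judge what
the package computes and what its tests do and do not demonstrate.

## Signal model and preprocessing

The analysis channel is a single ECG lead (lead II by convention),
uniformly sampled.  Preprocessing fixes a common working representation
regardless of acquisition hardware: extract lead → cut segment → resample
to 125 Hz → zero-phase low-pass.  The filter is a 4th-order Butterworth at
40 Hz applied forward and backward (`filtfilt` with symmetric extension of
3× the filter order per end), so the effective magnitude response is the
squared single-pass response — a tone exactly at the cut-off is attenuated
to 1/2 amplitude — and the net group delay is zero, which is what keeps
fiducial sample positions trustworthy.  Resampling uses polyphase rational
resampling with built-in anti-aliasing; 500 → 125 Hz is the clean 4:1
case.  The processing order (segment before resample/filter) follows the
acquisition workflow; away from segment edges the alternative order is
numerically indistinguishable for band-limited content.

## Beat annotation

The annotator is a deliberately simple derivative-threshold parser for
high-quality, low-heart-rate (25–90 bpm) sinus-rhythm strips.  All
thresholds are relative to signal statistics over the analyzed segment, so
annotation is invariant to amplitude scaling (gain) and insensitive to DC
offset.

* **R onset.** An onset at sample *i* requires `run_length` (5) consecutive
  samples with dV < 0.1·SD(dV) immediately followed by 5 consecutive
  samples with dV > 0.2·SD(dV).  The low test is signed: downslopes count
  as "low", which is what lets the Q-wave downstroke serve as the guard
  run before the QRS upstroke.  A 0.4 s refractory period suppresses
  re-triggers inside the same complex (the operating range tops out at
  90 bpm, i.e. ≥0.67 s cycles, so 0.4 s is safely below one cycle).
* **R peak.** Voltage argmax over (onset, onset + 0.12 s]; Q peak: argmin
  over [R − 0.10 s, R).  The windows are sized to the broad equine QRS and
  exposed in config.  All extremum searches break ties toward the earliest
  index, for determinism.
* **T wave.** Searched between 1/8 and 1/2 of the beat duration (forward
  RR) after R.  The T peak maximizes |V − median(window)|, which finds
  inverted T waves without a polarity assumption.  T end is the first
  index after the T peak where |dV| stays below `t_end_coef`·SD(V) for 5
  consecutive samples and must precede the next R.
* **Failure policy.** Any beat whose windows leave the signal, whose T end
  never settles, or whose fiducials come out of order is dropped
  individually (debug-logged); the segment is never aborted.  The last
  detected beat has no forward RR and is always dropped.

**T-end calibration.** The T-end rule only fixes the *form* of the
threshold (a multiple of SD(V) applied to |dV|).  The coefficient trades
early triggering near the T apex (too high) against never settling above
the noise floor (too low).  `scripts/calibrate_t_end.py` sweeps the
coefficient on synthetic recordings spanning the operating range at SNR
20 dB; the recovery curve has a plateau over ≈0.06–0.08 with median QT
error minimized near its center, and the package default is 0.07.

**Known behavior at the thresholds.** The onset rule has a dead band
between 0.1·SD(dV) and 0.2·SD(dV): a sample landing in it breaks both
runs.  On quantized data a small fraction of beats (≈2–4%, including
noise effects) deterministically misses detection this way; the
interval-level consequence is bounded by the beat filter and by the
≥95%-recovery acceptance test.

## Restitution intervals

Per beat *i* (with successor *i*+1): RR = R_{i+1} − R_i (cycle length),
QT = Tend_i − Q_i (a proxy for action-potential duration), and
TQ = Q_{i+1} − Tpeak_i.  Note the TQ convention starts at the T *peak*,
not the T end, so QT and TQ overlap by the Tpeak→Tend span; this is the
method's stated definition and is implemented verbatim rather than
"corrected" to a true diastolic interval.  Each triplet pairs the QT of a
beat with the same beat's forward TQ and RR.  Beats with RR or TQ not
strictly below 2.4 s are discarded; 2.4 s is exactly the cycle length of
the 25 bpm heart-rate floor, so the filter removes artifactual detections
rather than physiology.

## Classification

Beats are embedded in the 3D space (RR, QT, TQ) — or one of its 2D
projections — and z-scored column-wise by the mean and sample SD (n−1) of
the *real training beats only*, fitted once per cross-validation run and
applied unchanged to training, synthetic, and test beats.  Plain Euclidean
distance on z-scores is mathematically identical to standardized Euclidean
distance on raw intervals, so one code path serves both formulations (a
test verifies the identity numerically).

Class imbalance is corrected by SMOTE: each synthetic minority beat is
x + u·(x_nn − x) with u ~ U[0,1], x a minority beat drawn uniformly with
replacement (class ratios are not integer), and x_nn one of its
k_smote = 5 nearest minority neighbors, computed in the same normalized
space the classifier uses.  Oversampling runs to exact parity with the
majority class; majority rows are untouched.

The k-NN model stores the training matrix verbatim.  A query beat's
posterior is the PAF fraction among its k nearest neighbors; k is
restricted to odd values so the per-beat vote at threshold 0.5 cannot
tie.  Distance ties at the k-th neighbor resolve toward earlier training
rows (measure-zero for continuous features, deterministic always).  The
batch prediction path uses a tree-backed neighbor search and is tested
for exact agreement with an exhaustive full-sort oracle.

A subject's final label is the majority of its per-beat labels; the
subject-level score used for ROC analysis is the PAF vote fraction (the
mean posterior is also exported).  An exact 50/50 vote resolves to PAF:
in a screening context the tie should cost specificity, not sensitivity.

## Evaluation

Repeated random subsampling with stratification, always splitting by
subject: per run, `n_train_control` = 48 and `n_train_paf` = 7 subjects
(with all their beats) train; every remaining subject is held out (7 + 3
for the default 55 + 10 cohort).  Training-subject combinations are kept
unique across runs by rejection sampling on a seen-set, and the number of
requested runs is validated against the number of distinct combinations.
No beat of any test subject ever reaches normalization fitting, SMOTE, or
the stored model.

Metrics per run, k, and feature set: TPR and TNR (PAF positive) and
ROC-AUC via the rank/Mann–Whitney formulation with ties counted 1/2 —
beat-level on pooled test-beat posteriors, subject-level on vote
fractions.  Metrics undefined on a run (a degenerate test side) are
recorded as missing and excluded from summaries, with counts reported.
Run distributions are summarized as mean with 2.5th/97.5th percentiles
(linear-interpolation estimator) and the corresponding +/− offsets.

Paired beat-level vs subject-level comparisons use the two-sided Wilcoxon
signed-rank test.  Zero differences are dropped (≥5 non-zero pairs
required).  For n ≤ 25 the null distribution of W+ is computed exactly by
convolution over (doubled, hence integer) ranks — identical to
enumerating all 2ⁿ sign assignments; beyond that a normal approximation
with tie and continuity corrections is used.  Tests verify the exact
branch against literal 2ⁿ enumeration and both branches against an
independent implementation.

## Synthetic data

**Waveform generator.**  Each beat is a sum of five Gaussian components
(P, Q, R, S, T); ground truth records the analytic extremum positions and
defines the true T end as 2 T-widths past the T center (≈95% of the wave
area).  RR intervals are Gaussian around 60/HR with a configurable CV,
rejection-truncated to [60/90, 2.4) s.  Two features matter and are
deliberate design choices rather than cosmetic defaults:

* *Rate adaptation.*  P and T center offsets are specified at a 1.0 s
  reference RR and scale linearly with each beat's RR, keeping the T peak
  at a fixed ≈1/3 of the cycle — inside the detector's [RR/8, RR/2]
  window across the whole 25–90 bpm range, and emulating rate-dependent
  repolarization timing.  Q, R, S offsets are fixed (QRS duration varies
  little with rate).
* *Slope contrast.*  The default template has a deep, narrow Q feeding a
  tall narrow R (fast crossing of the onset rule's dead band) and small,
  slow P and T waves whose upstroke derivatives stay below the high-dV
  threshold — the morphology regime the derivative-threshold parser was
  built for.  Real equine lead II typically shows a larger T than this
  template; the template trades that for an unambiguous analytic ground
  truth under the parser's assumptions, and the parser's own tolerance to
  other morphologies is *not* established by these tests.

The generator's default sampling rate is 500 Hz (telemetric-recorder
emulation); tests and the acceptance script always run the full chain
(synthesize at 500 Hz → resample to 125 Hz → filter → annotate).  Noise
is white Gaussian plus sinusoidal baseline wander; `with_snr` sets the
noise SD to realize a target power SNR against the clean waveform RMS.

**Cohort generator.**  (RR, QT, TQ) triplets cluster around an inclined
plane: point = p₀ + s₁·b₁ + s₂·b₂ + n·n̂, with b₁ the RR-like direction
(encoding QT ≈ a + b·RR and TQ ≈ RR − QT couplings), b₂ a QT/TQ
trade-off direction, and n̂ the plane normal (σ_off = 0.01 s).  Subjects
receive a random offset along b₁ (resting-heart-rate differences,
SD 0.12 s); PAF subjects are additionally displaced by a shift vector,
by default along n̂ — the diseased substrate as a displacement of the
restitution manifold.  `class_shift` converts "δ pooled within-class SDs"
into that vector analytically.  Triplets violating positivity or the
2.4 s filter are rejection-resampled; a >99% rejection rate raises.  The
exact plane coefficients are configuration, not claims about equine
physiology.

Default cohort shape: 55 control / 10 PAF subjects with 500–800 usable
beats each (≈43 000 beats at full scale).  Calibration-style tests use
200 beats per subject and spread their CV runs over 8 independently drawn
cohorts of this shape: with only 10 PAF subjects, a single realized
cohort retains persistent sampling luck (the 200-run mean subject-level
AUC varies by ≈±0.1 across cohort draws even for a perfectly calibrated
classifier), and averaging over draws estimates the generator-level null
behavior.  These calibration cohorts also set the per-subject offset SD
to zero, because the property under test is stated for *identical*
(exchangeable) class distributions.

**What passing tests do not show.**  The generators emulate morphology,
rhythm variability, broadband noise, and baseline wander — not muscle
tremor, electrode motion, 50 Hz interference, arrhythmic beats, or
rate-dependent restitution curvature.  Fiducial-recovery results
therefore characterize the parser on clean-to-moderately-noisy sinus
rhythm only, matching its intended operating envelope; robustness on
pathological or artifact-laden traces is explicitly out of scope.
Likewise, classification results on synthetic cohorts demonstrate the
correctness and calibration of the pipeline, not clinical performance.

## Problem sizes

Test and acceptance workloads are sized for a single CPU: 20 simulated
60 s recordings for fiducial recovery; 50 training sets × 200 queries ×
8 k-values for the k-NN oracle; 8 cohorts × 25 runs per shift level
(δ ∈ {0, 0.5, 1, 2} pooled SDs at k = 13; k ∈ {3, 9, 21, 41} at δ = 0.5
for the aggregation-gain check); and a 20-run seeded pipeline rerun for
determinism.  The full-scale protocol (1000 runs, k = 3..41, four feature
sets) is available through `era3d crossval` with the default
configuration.

## Numerical conventions

0-based sample indices, half-open windows, intervals as index difference
divided by sampling rate.  SD(dV) and SD(V) are population SDs over the
analyzed segment (the thresholds are scale-free, so the ddof choice is
immaterial); feature normalization uses sample SD (n−1) as is standard
for fitted statistics.  Percentiles use linear interpolation.  All
randomness flows from explicit seeds through `numpy.random.Generator`;
every documented entry point is bit-deterministic given its seed, and
model serialization round-trips floats exactly (shortest-repr JSON).
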