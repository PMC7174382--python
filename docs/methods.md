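# Methods

## Problem and data model

The task is binary classification of RR-interval recordings: does the
series precede a ventricular tachyarrhythmia (VTA) onset, or is it normal
sinus rhythm? A recording is an ordered sequence of RR intervals in
milliseconds with an onset anchor at its end. Prediction must be made a
minute ahead, so features are only taken from the *required window*: the
interval sub-sequence whose cumulative end-times fall in (−360 s, −60 s]
relative to onset. The half-open side sits at the onset-distal boundary;
an interval ending exactly 60 s before onset lies wholly outside the
60 s forecast gap and is kept. Intervals straddling a boundary are
assigned by their end-time — one unambiguous rule, so window counts are
deterministic (420 one-second intervals with onset at the end yield
exactly 300 kept intervals).

## HRV features

Eleven features per window, all computed on the raw (un-resampled)
required-window series:

| feature | unit | definition |
|---|---|---|
| MeanNN | ms | arithmetic mean interval |
| SDNN | ms | population SD of intervals (sample-SD behind a flag) |
| RMSSD | ms | root mean square of successive differences |
| pNN50 | % | 100 · #{\|ΔRR\| > 50 ms} / N, strict inequality, denominator the total interval count N (the N−1 difference count behind a flag) |
| VLF, LF, HF | ms² | Welch PSD integrated over 0–0.04, 0.04–0.15, 0.15–0.4 Hz |
| LF/HF | – | band-power ratio; NaN when HF = 0 |
| SD1 | ms | √(½ · population Var of successive differences) |
| SD2 | ms | √(2·SDNN² − ½·SD1²), negative radicand clamped to 0 |
| SD1/SD2 | – | NaN when SD2 = 0 |

Spectral pipeline: the unevenly sampled series is cubic-spline resampled
onto a 4 Hz grid (the dominant HRV convention; rate configurable), the DC
offset removed, and the PSD estimated by Welch's method with a Hann
window, 256-sample segments and 50 % overlap. Band power is the
rectangular integral of the density over the band, so the sum over all
bands approximates the signal variance (Parseval, within Welch leakage —
verified to 5 % in tests). Population variance is used throughout because
the window is treated as the complete object of interest, not a sample
from a longer stationary record; the SD2 identity then holds exactly by
construction.

## Preprocessing and augmentation

- **Resampling.** The CNN requires a fixed input length. The interval
  sequence is interpolated against its beat index (0..N−1 mapped linearly
  onto 1000 points), linear by default so outputs stay within the input
  range; a cubic option exists. Index-based interpolation was chosen over
  cumulative-time interpolation as the simplest reading of "resample to
  1000 RR sample points"; both endpoints are preserved exactly.
- **Augmentation.** Each recording yields `multiplicity` (default 6, the
  value implied by the printed 261 → 1566 cohort growth) copies: the
  original plus shifted copies at offsets drawn uniformly from 1..N−1.
  A circular shift preserves the value multiset (MeanNN/SDNN exactly
  invariant) and exchanges exactly one successive difference (the split
  diff) for the wrap-around diff, which perturbs RMSSD/pNN50/SD1 slightly.
- **Outlier filter.** Recordings with LF/HF > 11.6 (the plausible upper
  bound for healthy autonomic balance; 10 available via config, reflecting
  an ambiguity in the source material's two stated thresholds) are
  removed after augmentation; undefined ratios (zero HF power) count as
  +∞ and are removed, since the downstream ratio feature is degenerate.
- **Order of operations.** Augmentation and the LF/HF filter act on the
  raw windowed series, and resampling to 1000 points happens last, per
  recording. Filtering resampled vectors instead would be meaningless:
  index-resampling stretches the tachogram time axis by N/1000, shifting
  oscillations out of their physiological bands.

## Classifiers

- **1-D CNN** (numpy, hand-written forward/backward): input 1000 points,
  standardized with a single scalar mean/SD estimated from the training
  split (the input is a homogeneous tachogram, so one affine rescale
  conditions the optimization without distorting shape). Four stacks of
  convolution (valid padding, stride 1; filters 3/10/10/10, kernels
  102/24/11/9) → ReLU → batch normalization → max-pool (size 2, stride 2),
  then flatten (460 units) → dense 22 → 22 → 1. Stride/padding/pool values
  are configurable defaults: only the filter counts and kernel sizes are
  fixed by the architecture description. Training is mini-batch Adam
  (lr 1e−3, batch 32, binary cross-entropy on logits, early stop after 10
  stagnant epochs); gradients are verified against numerical
  differentiation to 1e−5 in the test suite. Fits are bit-reproducible
  given the seed on a single thread.
- **ANN**: scikit-learn MLP, 11 → 22 → 22 → 1 (ReLU hidden, logistic
  output, 793 parameters), behind a StandardScaler fitted on training
  folds only.
- **SVM** (RBF, C = 1) and **KNN** (k = 5), also standardized. The SVM is
  scored through a logistic squash of its decision function — monotone, so
  ROC/AUC are unchanged and 0.5 maps to the margin boundary.

All hyperparameters beyond the architecture are conventional defaults
surfaced in `TrainConfig`/builder arguments.

## Evaluation

Stratified 10-fold cross-validation (unstratified available). Sensitivity
= TP/(TP+FN), specificity = TN/(TN+FP), accuracy, all in percent at a 0.5
score threshold; aggregates are fold means ± SD. ROC/AUC uses the pooled
out-of-fold scores with a trapezoidal threshold sweep, which equals the
tie-aware pairwise concordance probability (asserted to 1e−9 against a
brute-force oracle). Folds with single-class training data are flagged
and excluded from rate aggregation.

Augmentation interacts with splitting in two modes. `pre_split` (default)
augments the whole cohort before splitting; shifted near-duplicates of
one recording can then appear in both train and test folds, which
inflates instance-memorizing models (KNN most visibly). `fold_safe`
augments training folds only (applied to the CNN's input vectors; the
order-aggregated HRV features gain nothing from shifted rows). Reported
numbers under `pre_split` mode should be read with that caveat; both
modes exist precisely so the leakage is measurable.

Statistics: per-feature two-tailed Welch t-tests between classes (pooled
variance behind a flag), one-way ANOVA over per-fold accuracies across
algorithms (four algorithms × 10 folds → df (3, 36)) with Tukey HSD
post-hoc.

## Synthetic generator

Integral-pulse beat model:
`RR_i = m + lf_amp·sin(2π·0.1·t_i) + hf_amp·sin(2π·0.25·t_i) + ε_i`,
with `t_i` the cumulative beat time, `ε_i ~ N(0, noise_sd²)`, and a
200 ms positivity floor. The recording-level mean `m` is drawn once per
recording from `N(mean_nn, mean_sd²)`: cohort summary statistics
(mean ± SD across recordings) describe between-recording spread, and
without it every recording in a class shares one mean and any classifier
trivially separates the classes. Class defaults:

| parameter | VTA | control | rationale |
|---|---|---|---|
| mean_nn (ms) | 684.45 | 775.15 | class mean intervals (VTA faster) |
| mean_sd (ms) | 125.47 | 107.61 | between-recording spread |
| lf_amp, hf_amp (ms) | 30, 30 | 40, 30 | sinusoid-power LF/HF ratio 1.0 vs ≈1.78 (lower autonomic balance before onset) |
| noise_sd (ms) | derived | derived | chosen so total interval variance matches an SDNN target of 74.34 / 79.04 ms |
| duration (s) | 420 | 420 | leaves the full required window plus forecast gap |

Per-recording seeds derive from the master seed through a counter-based
`SeedSequence`, so datasets are reproducible and order-independent.

What the generator does **not** emulate: ectopic beats and artifacts,
nonstationarity within a recording, heterogeneity of the LF/HF structure
across recordings (amplitudes are fixed per class, which makes the
frequency features more cleanly informative than in real cohorts), and
any actual pre-arrhythmic dynamics. Passing tests therefore demonstrate
pipeline correctness and calibration — parameter recovery, chance-level
behavior under label permutation, count contracts — not clinical
predictive performance.

## Problem sizes and numerical choices

- Test-suite study conditions: the "separated" cohort is 25 + 25
  recordings at the class means with `mean_sd = 0` and 10 ms jitter
  (near-separable by construction; neural models must reach ≥ 90 %
  cross-validated accuracy); the calibration cohort is 100 + 100
  recordings at class defaults, where label-permuted accuracy is averaged
  over several permutations (5 for feature models, 3 for the CNN) and
  must sit at 50 ± 5 %.
- The acceptance script runs the full study at 45 + 42 recordings with
  8 CNN training epochs — a desk-scale cohort keeping the 135:126 class
  ratio.
- Ties and degenerate inputs: empty series and single intervals raise;
  constant series give zero dispersion features and NaN ratios; equal
  scores contribute half-concordance to AUC; a single-class truth flags
  the undefined rate as NaN rather than guessing.
- Determinism: every stochastic stage (generation, augmentation offsets,
  fold assignment, weight initialization, batch shuffling) draws from a
  seed fanned out from the single master seed via `SeedSequence`.

## Known limitations

- The `pre_split`-mode augmentation leakage (above) is kept as the
  default deliberately; fold-safe numbers are the methodologically sound
  ones.
- The MVTDB reader is convention-based (classifies files by `vt`/`vf` vs
  `control` path tokens, pairs by stem, converts seconds to ms when the
  median interval is below 10): it ingests MVTDB-style trees but has only
  been exercised on synthetic fixtures.
- Batch normalization uses batch statistics at train time; very small
  batches (< 4) make the CNN fit noisy.
- The CNN is CPU-bound numpy; it is sized for hundreds, not tens of
  thousands, of recordings.
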