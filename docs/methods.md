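# Methods

## Problem setting

The toolkit targets two-class subject-level discrimination from multichannel
resting-state EEG: each subject contributes one recording (default: 19-channel
10–20 montage, 256 Hz, 10 minutes) and a binary label (positive class:
MCI-like). Recordings are segmented, each segment is decomposed into
subbands, one scalar measure per sub-signal forms the feature vector, and a
classifier is scored under leave-one-subject-out (LOSO) cross-validation.
NSGA-II then searches channel or feature subsets jointly with classifier
hyperparameters, trading subset size against LOSO accuracy.

## Preprocessing

Band-pass 0.5–64 Hz, then common-average re-reference, then non-overlapping
segmentation (default 10 s); the order is fixed. The filter is a symmetric
(linear-phase) FIR designed with a Hamming window; the tap count follows from
a 0.25 Hz transition width at the low edge (≈3379 taps at 256 Hz) and the
filter is applied by FFT convolution with `same` alignment, which cancels the
group delay exactly (zero phase, unity passband gain). Odd-reflection padding
suppresses edge transients; a residual transient of roughly one kernel length
remains at each recording edge, negligible at the 10-minute recording scale
(stopband leakage ≈1 % RMS for a pure out-of-band tone). Segments shorter
than the nominal length at the recording tail are discarded. Line-noise
removal, ICA and artifact rejection are out of scope: inputs are assumed
clean (or synthetic).

## Subband decomposition

**VMD.** The variational problem (modes with compact spectral support around
learned center frequencies) is solved by the standard ADMM scheme in the
frequency domain: the signal is mirror-extended on both sides, only
non-negative frequencies are retained, and each iteration updates every mode
by Wiener-like filtering around its center frequency followed by the
power-weighted centroid update of the center frequency. Defaults: K = 5
modes, bandwidth penalty α = 2000, dual step τ = 0 (no strict reconstruction
enforcement, robust to noise), tolerance 1e-7 on the summed relative mode
change, 500 iterations maximum, uniformly spaced initial center frequencies,
no DC mode. Modes are reported sorted by descending center frequency (VMF1 =
fastest); the residual is defined as input minus mode sum, so conservation is
exact by construction. A convergence flag and iteration count are returned;
non-convergence yields the best iterate.

**DWT.** Standard multilevel transform (PyWavelets), default `db4`, 5 levels,
symmetric (mirror) boundary handling. Detail level j occupies
(fs/2^(j+1), fs/2^j]; the approximation [0, fs/2^(levels+1)]. Features are
computed on the coefficient vectors; a reconstruction-based variant (features
on band-limited time signals) is available behind `use_reconstruction`.

For feature extraction, VMD contributes [VMF1..VMF5, residual, original] and
DWT [A5, D2..D5, original]; D1 (64–128 Hz) is excluded because the band-pass
leaves it without physiological content.

## Measures

Exactly one measure is used per feature matrix (measures are investigated
individually, not fused). Definitions are in the `features` module docstring;
the non-obvious choices:

- **ThEn/SuEn threshold** ε defaults to 0.2 × sample SD of the sub-signal
  (scale-adaptive; a fixed absolute ε is configurable). No canonical value
  exists for these threshold entropies on EEG; a relative threshold avoids
  unit dependence.
- **TShEn** is implemented as Shannon entropy of a 16-bin amplitude histogram
  over [min, max] — an amplitude-distribution entropy, deliberately distinct
  from the energy-based ShEn. Other conventions exist for
  "transformation-Shannon entropy"; this one is a documented default, flagged
  as such.
- **KFD** uses the (index, amplitude) curve with unit index spacing, path
  length L = Σ√(1+Δx²) and d = max Euclidean distance from the first curve
  point, so a straight ramp gives exactly 1. **HFD** uses kmax = 10 and a
  least-squares fit of log L(k) against log(1/k).
- Degenerate inputs: zero-energy signals get ShEn = 0; constant signals get
  TShEn = 0 (single occupied bin) and KFD = 1 (a line).

## Classifiers and evaluation

- **RF**: 30 bagged decision trees; tuned parameter: depth 1–35. Bagging seed
  is the evaluation seed (the only stochastic learner).
- **SVM**: least-squares SVM, solved as the Suykens dual linear system with
  fixed C = 0.2; tuned parameter: kernel ∈ {linear, polynomial (degree 3),
  RBF}. The RBF bandwidth uses the median-pairwise-distance heuristic on the
  training fold (capped subsample of 500 rows for O(n²) safety).
- **DA**: linear or quadratic. QDA uses sklearn with a small regularization
  ladder and falls back to an in-package trace-scaled ridge Gaussian QDA when
  a class covariance is rank-deficient (class count ≤ feature count), which
  small cohorts and large masks can produce.
- **KNN**: k ∈ 1–10 and ten distances indexed 1–10 (euclidean, seuclidean,
  cityblock, chebychev, minkowski, mahalanobis, cosine, correlation,
  spearman, hamming). seuclidean/mahalanobis use training-fold
  variances/ridge-regularized covariance; spearman is correlation distance on
  per-row rank transforms; minkowski uses exponent 3 (to be distinct from
  euclidean).

Features are z-scored per fold with training statistics for SVM/KNN/DA; trees
see raw features. LOSO yields one fold per subject; CA is the unweighted mean
of per-fold accuracies (×100). Because each LOSO test fold is single-class,
sensitivity/specificity/precision/F-score are computed from confusion counts
pooled across folds (zero denominators give 0 with a flag). The pooled
accuracy is also reported; it equals the per-fold mean only for equal fold
sizes. A segment-level stratified k-fold evaluator is provided solely as the
leakage contrast.

## NSGA-II selection

Channel mode attaches one binary gene per montage channel (a selected channel
contributes all its subband columns); feature mode one gene per (channel,
band) column. Hyperparameter genes ride along (KNN: 2; others: 1).
Objectives: minimize selected-count, maximize LOSO CA (internally minimized
as 100 − CA); the No_ch ≥ 1 constraint is enforced by repairing all-zero
masks (one uniformly random gene flipped to 1).

The loop is canonical elitist NSGA-II: fast non-dominated sort, crowding
distance (boundary solutions +∞, interior normalized neighbour gaps), binary
tournament on (rank, crowding), uniform crossover on mask genes (pair rate
0.9), per-gene bit-flip mutation (rate 1/n_mask), single-point exchange plus
random-reset mutation (rate 0.1) on parameter genes, and (μ+λ) environmental
selection. These operator choices are standard mixed binary/integer GA
practice; no claim is made that they match any particular prior
implementation. Fitness is memoized on the decoded (mask, params) key with a
fixed inner LOSO seed, so it is a pure function within a run, duplicate
genomes are free, and unique evaluations are bounded by
pop_size × (max_iter + 1). Runs are deterministic given the seed. Reference
budgets for full-scale studies are population 200 / 50 iterations (channels)
and 1000 / 100 (features); tests and examples use population 32 / 30
iterations, which suffices for ≤ 8-channel problems (verified against
exhaustive enumeration on 6-channel problems).

"Best" front solution for headline reporting is the maximum-CA member, ties
broken by smaller subset.

## Synthetic cohorts

Each channel is a sum of band-limited filtered Gaussian noise components (one
per canonical band: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–64 Hz, with a fixed 1/f-flavoured amplitude profile) plus broadband
Gaussian noise. Class effects are planted by splitting a channel into its
content inside the effect band and the remainder and scaling the in-band part
by √power_ratio, so the realized Welch band-power ratio tracks power_ratio
(verified to ±30 % at 600-s durations). Multiple effects (e.g. opposite-signed
contrasts on different channels) can be combined.

Three per-subject nuisance factors emulate inter-subject variability, all
lognormal and label-independent: a global amplitude gain shared by all
channels (`subject_gain_sd`, default 0.3), an independent per-channel gain
jitter (`channel_gain_sd`, default 0.1), and per-band amplitude factors
shared across channels (`band_profile_sd`, default 0.25) giving each subject
an idiosyncratic spectral profile. Per-subject streams are children of the
master `SeedSequence` spawned by subject index, so cohorts are bitwise
reproducible and subjects independent.

What the generator does **not** model: volume conduction and realistic
spatial covariance, artifacts (ocular, muscle, line noise), nonstationarity
within a recording, and any physiologically calibrated MCI signature.
Passing recovery tests therefore demonstrate correctness of the machinery on
controllable ground truth, not clinical performance on real EEG; headline
accuracies from real datasets are outside what this package can or does
reproduce.

## Reference experiments

- **Recovery** (`experiments.recovery_*`): 24 subjects (11 positive / 13
  control), 8-channel montage, 60-s recordings, theta power ×4 on T5 and ×1/4
  on O1 for the positive class, confound sds (0.3 global, 0.05 channel, 0.35
  band profile). The opposite-signed contrast makes every single channel
  intrinsically confounded by the subject's own theta level while the exact
  planted pair cancels it, so the size-2 pair is the Pareto-optimal target of
  channel-mode NSGA-II — a well-posed recovery question. DWT Teager-energy
  features, KNN family, population 32 × 30 generations. The 8-channel montage
  and 60-s duration are the package's reference problem size for this
  experiment; the contrast does not depend on the full 19-channel, 10-minute
  layout.
- **Leakage**: a null cohort (power_ratio 1) whose subjects differ only in
  amplitude gains; segment-level 10-fold CV scores far above LOSO (which
  stays at chance), quantifying subject-identity leakage.
- **Chance floor**: subject-level label permutation under LOSO.

## Known limitations

- VMD center-frequency estimates on short, noisy segments depend on α and K;
  the printed per-segment center frequencies of any one decomposition are not
  stable study-level quantities.
- The LS-SVM solves a dense (n+1)×(n+1) system; beyond ~5000 training
  segments this becomes the pipeline bottleneck.
- Feature-mode NSGA-II at full budget (population 1000 × 100 iterations with
  LOSO in the loop) is computationally heavy by design; expect long runs on
  one CPU at the 114/133-gene scale.
- Sensitivity/specificity pooling across LOSO folds is a deliberate,
  documented divergence from per-fold averaging, which is undefined for
  single-class test folds.
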