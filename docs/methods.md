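# Methods

## Pipeline model

The package treats behavior recognition as windowed supervised
classification of six-channel inertial signals. The stages, and the
assumptions each one makes, are:

1. **Decimation.** Lower sampling frequencies (500/250/100/50 Hz from a
   1000 Hz master) are obtained by keeping the first sample of every d =
   SF/target samples, with no anti-alias filtering or interpolation, and
   kept samples retain their original timestamps. This mirrors how
   multi-rate comparisons are done when the question is "what would this
   sensor have recorded at a lower rate", not "what is the best
   band-limited representation". Decimation composes:
   downsampling 1000→100→50 equals 1000→50.

2. **Windowing.** Windows contain WS samples (a power of two, for FFT
   friendliness), last WL = WS/SF seconds, start at each labeled
   interval's start, and slide by WS/2 (50 % overlap). A window is
   emitted only when all WS samples fall strictly inside its interval
   (labels are end-exclusive: a sample at exactly the interval end
   belongs to the next behavior). Intervals shorter than WL therefore
   contribute nothing; with a 1.28 s window this is the operative
   constraint for sub-second behaviors. Two instance-count
   standardizations are provided: `equalize_counts` under-samples per
   class to explicit targets (the EQ condition for half-size-window
   comparisons), and `standardize_across_sf` subsamples each
   (class, hen) cell down to its 50 Hz count so sampling-frequency
   comparisons are not confounded by instance counts. Subsampling per
   cell rather than per class keeps both the class and the individual
   distribution comparable across SFs.

3. **Features.** 13 statistics × 7 axes + 6 axis-pair correlations = 97.
   Estimator conventions (any consistent choice preserves the geometry;
   these are the simplest deterministic picks):
   * moments are population forms (divide by N, no bias correction);
     kurtosis is excess (normal → 0); skewness and kurtosis of a
     zero-variance signal are defined as 0;
   * IQR uses linear-interpolation quantiles;
   * mean crossings count sign alternations of the mean-removed signal
     with exact zeros mapped to +, so a constant window crosses 0 times;
   * frequency features (spectral energy, frequency entropy in nats,
     dominant frequency in Hz) come from the one-sided DFT of the
     mean-removed signal, bins k = 1..N/2, rectangular taper. Removing
     the DC bin keeps the gravity component out of the spectrum — the
     static posture information lives in the time-domain means, and the
     dominant frequency of quiet postures would otherwise be a
     degenerate 0-bin for every class. Dominant-frequency ties resolve
     to the lowest bin; an all-zero spectrum yields energy/entropy/
     dominant frequency 0;
   * correlations with a zero-variance axis are 0, keeping all vectors
     finite.
   The magnitude axis m = √(x²+y²+z²) is recomputed per window from the
   acceleration samples and is invariant under any common rotation of
   the acc axes, which the tests verify directly. Feature order is fixed
   (axis-major, symbols in a fixed list, then correlation pairs) so
   serialized tables are reproducible. Subsets: ACC (55), GYR (42), and
   two readings of "without magnitude" — removing the 13 m-features from
   the full bank (84) or from ACC (42); both are exposed because the two
   descriptions in circulation disagree, and nothing downstream depends
   on adjudicating. Two literature feature sets are provided for
   comparison: a 4-feature set (entropy + mean of acc x/y) and a
   31-feature accelerometer set (9 statistics × 3 axes + 3 population
   covariances + mean signal magnitude).

4. **Balancing.** SMOTE raises minority classes to the majority count by
   x + u(x′−x) interpolation between a minority point and one of its
   k = 5 nearest same-class neighbors (u ~ U(0,1)); classes smaller than
   k+1 fall back to k = count−1, and singleton classes are an error.
   SMOTE+ENN then removes every instance (any class) whose label loses
   the majority vote of its k = 3 nearest neighbors in the post-SMOTE
   set; a tie involving the instance's own label keeps it. The defaults
   follow the conventional implementations of these methods. Balancing
   runs independently inside every training partition — including inner
   tuning splits — and a provenance flag plus an in-harness audit
   guarantee synthetic points never reach validation or test data.
   Distances are measured in the space the downstream classifier sees:
   standardized features for scaling families, raw features for trees.

5. **Classifiers and nested CV.** Seven families behind one contract:
   GaussianNB, kNN (k 1–10 × uniform/distance), decision tree (depth
   {5,7,10,12,15,20} × gini/entropy × best/random), random forest
   ({100,200,300} trees × gini/entropy × depth {5,10,50} × sqrt/log2),
   LightGBM (min_child_samples {0,5,15,300} × num_leaves {15,31,127} ×
   L1/L2 {0,0.1,1,10}), linear SVM (C {0.01,0.1,1,10}), and a one-hidden-
   layer MLP ({50,75,100} units × lr {1e-4,1e-3,1e-2} × alpha
   {1e-5,1e-4,1e-3}, early stopping). Unlisted hyperparameters stay at
   the backing library defaults. Standardization (train mean/SD, zero-SD
   features centered only) is skipped for the tree families, which are
   scale-equivariant. Tuning is exhaustive over the grid, scored by mean
   macro-F1 over a stratified inner 5-fold CV of the outer training
   partition — macro-F1 because it is the pipeline's primary metric —
   with ties going to the earlier candidate in grid order. When the
   smallest training class has fewer members than the fold count the
   inner CV degrades gracefully (fewer folds, then no CV at all), with a
   logged warning. Outer schemes: stratified 10-fold (fold membership
   depends on the seed) and LOHO (folds fixed by the hen ids; the test
   hen is excluded from tuning and training by construction). A class
   missing from a training partition — possible under LOHO with rare
   behaviors — is tolerated with a warning; its test windows then count
   as errors.

6. **Evaluation.** Metrics are computed from the element-wise mean of
   the per-fold count matrices (equivalently their sum — the metrics are
   invariant to positive scaling, which the tests check). Zero
   denominators (class never predicted / never tested) define the
   affected metric as 0 and still enter the 12-class macro average, so
   macro values always average a fixed number of classes. IIR with a
   zero 10-fold denominator is returned as flagged-undefined rather than
   raising. Report tables round to 3 decimals, duration summaries to 1,
   matching conventional presentation; duration SD uses the population
   estimator (the sample estimator differs by < 1 % at the interval
   counts involved, and nothing downstream consumes the SD).

## Synthetic data

The generator emulates what matters to the pipeline, not hen physiology.
Defaults: 8 hens, 1000 Hz native sampling, 240 s sessions; per-class
episode durations are gamma distributed with the mean/SD of the observed
per-class duration statistics of a real flock (from 1.3 s body-shaking
bursts to ~90 s resting bouts), truncated to [0.3 s, 20 s] so a desk-
scale session is not swallowed by one resting bout; episode classes are
drawn i.i.d. with probabilities proportional to the observed interval
counts (≈28:1 most-to-least frequent), after a per-session quota of 3
episodes per class scheduled in one-per-class rounds so rare classes are
present even in short sessions. Signals are gravity (9.80665 m/s²,
body-frame z-up) rotated by per-class posture (resting 60° and
dust-bathing 50° tilts vs upright standing) plus a class motif — impulse
trains at class-specific rates/amplitudes/directions for
eating/drinking/preening/litter-scratching/dust-bathing/others,
oscillations at 12/8/6 Hz for body shaking / head scratching / tail
flapping (all inside the one-sided spectrum at 100 Hz so the dominant
frequency is discriminative by design), a 2 Hz step cadence for moving —
plus white noise (SD 0.15 m/s², 1.5 deg/s), clipped to the ±2 g /
±500 deg/s sensor ranges. Per-hen effects are a random mounting tilt
(SD 5°), an amplitude gain (SD 0.1), and an impulse-rate multiplier
(SD 0.1). All randomness flows from one seed through named substreams,
so outputs are bit-reproducible and adding draws to one stage never
shifts another.

What passing tests on this generator show: the pipeline's mechanics
(segmentation, features, leakage-free CV, metrics) are correct, and the
LOHO/10-fold gap responds to individual effects in the expected
direction. What they do not show: field-accuracy on real hens, whose
within-class variability, transition structure, and sensor artifacts the
generator deliberately omits.

`make_separable_featureset` skips the signal stage entirely: Gaussian
class clusters at a configurable separation with additive per-hen
offsets, used for balancing/CV/evaluation tests where running the full
signal path would only add noise and runtime.

## Numerical and design choices

* Window anchoring at interval starts (not a recording-global grid) —
  the rule that guarantees windows never mix behaviors; boundary-
  crossing windows are discarded rather than majority-labeled, and no
  partial flush window is emitted at interval ends.
* Episode sequence is i.i.d. — behavioral Markov dynamics would not
  change anything the pipeline measures at window scale.
* Seeds for library estimators (RF/LGBM/MLP, fold shuffling) are 31-bit
  integers derived from the pipeline seed per named substream.
* Problem sizes in the test suite (240 s sessions at 100 Hz, ≈2500
  windows; 20-seed Monte-Carlo for the IIR-monotonicity check) were
  chosen as the smallest scales at which the checked effects are stable
  across seeds.

## Known limitations

* The first-sample decimator aliases by construction; it reproduces the
  multi-rate comparison design, not a resampling best practice.
* Cross-SF standardization assumes the 50 Hz condition is present and is
  a no-op for cells already at or below the reference count.
* LOHO with very rare classes can leave a class entirely out of a
  training fold; results for such classes reflect that honestly rather
  than being imputed.
* The CLI stores windows as a manifest (hen, class, start, WS, SF) and
  re-cuts them in `featurize`; this keeps artifacts small and textual
  but assumes the decimated recordings are unchanged between stages.
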