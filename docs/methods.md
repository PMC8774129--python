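# Methods

This note documents the models, procedures and numerical choices
behind `ncscreen`, and what its synthetic benchmarks do and do not
demonstrate about real screening cohorts.

## Synthetic cohort model

Real pan-cancer TPM matrices are non-negative, heavy-tailed, sparse,
and severely imbalanced. The generator emulates those properties with
the simplest law that has them:

* **Background expression.** Each entry is log-normal:
  `TPM = exp(N(base_log_mean, base_log_sd))` with defaults
  `base_log_mean = 1.0`, `base_log_sd = 1.2` (natural log), putting the
  median background near 2.7 TPM with a long right tail.
* **Dropout.** Each entry is independently forced to exactly 0 with
  probability `dropout_rate` (default 0.3), emulating unexpressed
  genes. Dropout is multiplicative noise, not a censoring model.
* **Planted signal.** `n_informative` features are chosen uniformly at
  random (from a stream tied to the cohort seed only, so paired
  cohorts plant identical markers). Each is assigned a target cancer
  class round-robin and its log-mean is shifted by `+effect_size`
  inside that class; `effect_size = 3` means roughly a 20-fold median
  increase. Shifts act on the log scale, so values stay non-negative
  for any effect size.
* **Imbalance.** `samples_per_class` lists the normal class first; the
  helper `study_scale_config()` reproduces the targeted cohort layout
  (26 cancer types, 8425 cancer vs 632 normal samples, ~13:1), while
  tests run the same law at 150–240 samples.
* **External cohorts.** `generate_paired_external_cohort` draws fresh
  samples from the same law with 1.5× the base log-sd (independent
  validation data are reliably noisier than discovery data) and renames
  all but `round(shared_fraction × n_features)` feature identifiers,
  emulating a different platform or annotation release. The inflation
  factor is a fixed documented constant, not a fitted quantity.

What the generator deliberately omits: batch effects, read-level
noise, gene–gene correlation, survival times, and any exosome-specific
biology. Passing tests on these cohorts demonstrates that the
pipeline's machinery (selection, ranking, training, the turning-point
scan) behaves correctly and recovers known structure; it does not
certify performance on real tissue or blood data.

## Data handling

Expression values are carried through exactly as printed: reads never
normalize, filter or transform (parsing uses correctly-rounded float
conversion, and writes use `%.17g`, so a write/read round-trip is
bit-exact). The split convention is `|test| = ceil(test_frac·N)`,
`|val| = ceil(val_frac·(N − |test|))`, remainder training; the ceiling
is deliberate — it reproduces the 1812/1449/5796 partition of a
9057-sample cohort at 20%/20% — and splits are uniform over samples
with stratification available but off by default. Marker panels are
ordered by non-increasing frequency score with ties broken by
ascending feature identifier; panel intersection against a cohort
matches identifiers as exact strings and drops missing markers rather
than zero-imputing them (a model retrained on the matched subset is
the honest external test).

## Stability selection

Within a training cohort, each iteration randomly partitions the
samples into `m` disjoint subgroups of equal size ±1; the base
selector fits each subgroup and the features with nonzero coefficients
count as selected for that run. Defaults `m = 2`, `n = 100` (200 runs);
the frequency score is count/completed-runs, and the "final" set
contains features at or above `consistency_threshold` (default 1.0,
i.e. selected in every run).

Numerical choices:

* The base selector is an L1-penalized linear SVM (squared hinge,
  liblinear) fitted one-vs-rest, with the union of per-class supports;
  an L1 logistic alternative is pluggable. `regularization_strength`
  is the penalty weight (inverse of scikit-learn's `C`).
* Features are standardized *inside* each subgroup fit. Raw TPM spans
  orders of magnitude, and an unscaled L1 penalty would select by
  abundance rather than association; standardization is internal to
  the selector and never alters the data.
* Coefficients below 1e-8 in absolute value count as zero (liblinear
  leaves occasional non-exact zeros), and the liblinear RNG is pinned
  so a fit is a pure function of data and parameters.
* Subgroups containing a single class are skipped and excluded from
  the run denominator; counting them as non-selections would bias
  every frequency score downward for reasons unrelated to the
  features.
* `rank_for_multiclass` repeats the whole procedure on independent
  training resamples (default 8), each with its own derived seed and
  its own test/validation split; held-out samples never participate in
  selection.

## Classifiers

Two fixed architectures, implemented as a seeded numpy feed-forward
network so that weights, per-epoch histories and predictions reproduce
bit-for-bit:

| task | hidden layers | output head |
| --- | --- | --- |
| binary | 30, 60 | 1 sigmoid unit |
| multiclass | 240 × 6 | C-way softmax |

Every hidden layer uses relu followed by inverted dropout at rate 0.1;
the loss is the matching cross-entropy; the optimizer is Adam at its
standard settings (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8); training runs
exactly 30 epochs in batches of 20 with per-epoch reshuffling and no
early stopping. Weights use He-normal initialization (relu-appropriate);
biases start at zero. History entries are evaluated at epoch end with
dropout disabled, on the full training and validation sets. A
non-finite loss aborts with a diagnostic suggesting the `log_transform`
flag, since raw TPM scales vary over orders of magnitude. Gradients
were verified against central finite differences to ~1e-10.

Baselines (`random_forest`, `decision_tree`) are scikit-learn
estimators at library defaults, seeded, behind the same train/predict
surface; their "losses" in accumulation curves are post-fit
cross-entropies of predicted probabilities (clipped at 1e-12), so
curve artifacts stay finite and comparable.

No class weighting is applied despite the ~13:1 imbalance; the binary
screen is evaluated by AUC, which is insensitive to prevalence, and a
weighting option would change the system under study.

## Evaluation

* **AUC** is defined as the Mann–Whitney concordance computed from
  mid-ranks (ties count half). The trapezoidal area under the
  threshold-sweep ROC is the independent cross-check; the two agree to
  1e-12 on random instances by construction of both.
* **Kruskal–Wallis**: H on mid-ranks with the standard tie correction
  `1 − Σ(t³−t)/(N³−N)`, p from the χ² approximation with k−1 degrees
  of freedom. All-identical observations return (0, 1) rather than an
  error — constant accuracy traces are a legitimate "no divergence"
  outcome, not a failure.
* **Accumulation curves** train a fresh model per marker count on the
  training split and score the test split; the grid may be thinned
  (`ks=`) for large panels.
* **Turning point.** A single accuracy per run per count makes the
  per-count test degenerate (singleton groups), so each run
  contributes its trailing window of accuracies (default `window = 10`
  counts) as one group. `k_star` is the largest count k with
  p(j) ≥ α for every testable j ≤ k — the last point before sustained
  run-to-run divergence — and the result is flagged not-found if the
  first testable count is already significant. Larger α can only stop
  the scan earlier, so k\* is monotone non-increasing in α. The window
  length trades sensitivity (short windows are noisy) against lag
  (long windows blur the break past it); the detected k\* can land up
  to `window − 1` counts after a true break, which is why constructed
  break-at-50 traces yield k\* in [50, 60) at window 10.
* **Model comparison** runs all three model kinds on identical splits
  and panels and applies the same Kruskal–Wallis test across their
  metric traces.

## Pipeline and reproducibility

A run derives every stage seed from the master seed by hashing the
stage name (sha256, reduced below 2³¹), so stages are independently
reproducible and adding a stage never perturbs the others. All
artifacts are plain text (TSV/CSV/JSON) and the run log records seeds,
parameters and input checksums; reruns with identical config are
byte-identical. External validation retrains on the intersected marker
subset — the alternative (zero-padding missing inputs) feeds the model
values it never saw in training — and scores the whole external cohort
raw; a matched count below 10 markers is flagged as low-overlap, since
small panels make the screen visibly unstable.

## Problem sizes

The bundled tests and the acceptance script run the full pipeline at
desk scale: cohorts of 150–240 samples with 56–200 features, 8
resamples, accumulation grids up to K = 30, and selection at
m = 2, n = 25–100. These sizes were chosen so the complete suite runs
in a few minutes on one CPU while leaving every statistical behaviour
of interest (marker recovery, null calibration, turning-point
detection, no-signal controls) measurable; the library itself has no
scale-specific logic and accepts cohort-scale inputs unchanged.

## Known limitations

* The generator's independence across features means selection
  problems here are easier than in real transcriptomes, where
  co-expression creates correlated decoys.
* The turning-point windowing is one defensible reading of "compare
  the runs at each count"; both `window` and `alpha` are exposed as
  configuration because the choice is genuinely open.
* Multiclass performance is plain accuracy; macro-averaged metrics are
  out of scope.
* Identifier matching is exact-string; cross-annotation mapping (e.g.
  gencode version lifting) is a non-goal.
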