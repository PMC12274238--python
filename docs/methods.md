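# Methods

This note documents the models and procedures implemented in `gestseg`,
the parameters that matter, and the design decisions taken where the
problem admitted several reasonable choices.

## Annotation model

Gesture annotations are event lists: one `(gesture, start_s, stop_s)` row
per occurrence, grouped per video, in the style of BORIS event-table
exports. Column names and delimiter are configuration (`TableDialect`)
because export layouts vary across software versions. Five gesture classes
are modeled (G1 regular dissection, G2 hemostatic control, G3 clip
application, G4 needle handling, G5 suturing) plus a background state
(label 0) for spans where no gesture is being performed; G1–G3 form the
dissection group (allowed in the BND and NVBD part-procedures), G4–G5 the
suturing group (allowed in UVA).

Rasterization to per-frame labels uses **frame-center sampling**: frame
`f` takes the label of the event containing time `(f + 0.5)/fps`, with
half-open event intervals `[start, stop)`. This avoids double-assignment
at boundaries and makes events→labels→events a near-identity (boundaries
recovered to within one frame; this is property-tested). Events of the
same class may not overlap; overlapping events of *different* classes are
resolved in favor of the later-starting event — "the action the surgeon
has moved on to" — with a warning, since an annotator logs one current
action at a time.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, so that
every downstream stage can be tested without external data:

* **Cohort**: 10 novice + 7 experienced surgeons, up to 3 repetitions of
  each of 3 part-procedures (default 153 videos). Default video length is
  956 s (the emulated study's 161 videos span 2565 min). Each track is
  drawn from an independently spawned RNG stream keyed by (surgeon,
  procedure, repetition), so cohorts are reproducible under a seed and
  stable under changes of cohort size.
* **Gesture scripts**: a Markov chain over the procedure's allowed
  classes (uniform transitions with a 0.25 relative weight on immediate
  self-repeats), **lognormal durations** with mean 9.6 s and log-scale
  σ = 0.5 — positive and right-skewed, which matches how surgical action
  durations are distributed; the empirical mean over ≥500 sampled events
  is tested to stay within 10% of 9.6 s. Background gaps between gestures
  are exponential with mean 2 s, since real annotation timelines contain
  "no gesture" spans. Experience level is metadata only by default: there
  is no published quantitative skill effect to emulate, and keeping
  novices and experts statistically identical makes the grouped-fold
  ratio invariants testable in isolation.
* **Features**: a Gaussian class-conditional model standing in for a
  frozen image encoder. Each of the six states has a fixed mean direction
  at distance `separation × noise_sd` from the origin in `dim`-dimensional
  space (default dim 128, matching the built-in histogram extractor);
  frames scatter with isotropic noise `noise_sd`. Noise is temporally
  smoothed with a **variance-preserving** moving average (window 5) so
  consecutive frames are correlated the way encoder features of adjacent
  video frames are; smoothing is applied to the noise only, so the
  `noise_sd → 0` limit decodes labels exactly and gesture boundaries stay
  crisp.
* **Frames**: procedural class-conditioned textures (distinct base hue,
  moving stripes, seeded pixel noise) at configurable resolution. These
  exist so the image path (ingest, extractors, palettes) can be tested on
  pixels; no photorealism is intended.

What passing tests on this cohort show: that the pipeline's machinery —
windowing, training, assembly, thresholding, metrics — is correct and that
the head can learn temporally structured, class-separable features. What
they do not show: performance on real surgical imagery, where class
separability is far lower, appearance drifts within a class, and the
feature extractor choice dominates.

## Feature extraction

Extractors are frozen, pure functions of pixels satisfying a small
contract (declared input range, constant output dimension, deterministic).
Two built-ins need no downloaded weights: `histogram` (three 32-bin
per-channel intensity histograms plus a 32-bin gradient-magnitude
histogram, dim 128) and `patchstat` (7×7 grid of per-patch mean/sd per
channel, dim 294, with symmetric patch edges so a 180° rotation permutes
the statistics). Pretrained backbones plug in through the same contract
via `register_extractor`; the Monte-Carlo comparison harness
(`compare_extractors`) draws the same surgeon-grouped random splits for
every candidate and reports mean ± sd validation accuracy.

## Classification head

A single-layer LSTM with 128 hidden units reads a 25-frame feature
sequence; a fully connected layer maps each hidden state to a softmax over
the six states. The loss is cross-entropy averaged over frames (sequences
that straddle a gesture boundary simply carry mixed frame labels).
Training is full BPTT with Adam (lr 3e-3, batch 128 by default), gradient
clipping at norm 5, forget-gate bias initialized to 1, Glorot-uniform
weights, ≤30 epochs with early stopping on validation loss (patience 5,
best weights restored). Inverse-frequency class weighting is available
(`class_weight="balanced"`) but off by default. Everything is plain
NumPy, so runs are bit-reproducible from `random_state` on any CPU.

The estimator follows scikit-learn conventions (`fit`/`predict_proba`/
`get_params`; fitted attributes end in `_`), so it composes with sklearn
tooling; `fit` accepts an explicit `validation_data` pair for grouped
protocols and otherwise holds out `validation_fraction` of sequences.

## Cross-validation

The sevenfold plan assigns whole surgeons: each fold's test set contains
exactly one experienced surgeon plus a round-robin share of novices, the
union of test sets partitions the cohort, and the validation set reuses
the next fold's test surgeons so train/val/test are mutually
surgeon-disjoint. Since all surgeons contribute the same number of videos,
surgeon-level round-robin keeps each fold's experienced:novice video ratio
within one surgeon's worth of the global ratio.

## Inference

Windows of 25 frames slide with stride 10 (15-frame overlap). The first
window's predictions are retained for all 25 frames; every later window
contributes only its last 10 — the frames for which the LSTM has the most
left context. The retained spans tile the video exactly (property-tested
for all lengths 1–500), so no overlap resolution is needed. A final
partial window is padded by repeating the last frame and the padded
predictions are dropped.

The per-frame softmax rows are then refined sequentially by Bayes'
theorem: the posterior at frame `f` is proportional to `prior_f ×
likelihood_f`, where `prior_f` is the renormalized mean of the previous 25
posteriors (uniform at the first frame). This is a deliberate
interpretation choice: a whole-video re-weighting (single Bayes update of
all frames against a global prior) is the other defensible reading, but
the sequential form preserves causality, is the identity under uniform
likelihoods, and converges monotonically under constant evidence (both
verified by tests). Rows are floored at 1e-12 before renormalization;
argmax ties break toward the lower class index.

## Post-processing

Per gesture class, one-vs-rest: the probability signal is linearly
interpolated onto a fixed 1000-bin (per-mille) timeline, smoothed with a
centered 25-bin moving average (edges reflected), and binarized by
hysteresis with thresholds `adaptive ± 0.1`. The adaptive threshold is

```
threshold(b) = base + γ · (0.5 − H(b)),   clamped to [0.05, 0.95]
```

with `base = 0.5`, `γ = 0.4`, and `H(b)` the mean binary entropy (base-2,
in [0, 1]) of the signal over a centered 51-bin window. A maximally
uncertain neighborhood (H = 1) thus relaxes the threshold to 0.3; a
deterministic one (H = 0) tightens it to 0.7. Binary per-class entropy is
the default because the thresholded signal itself is the per-class
probability; the full-distribution (6-class, normalized) entropy variant
is available via `entropy_mode="full"`. The numeric constants (γ, window
lengths, base) are package defaults chosen to give stable, qualitatively
sensible segmentations on the synthetic cohort; all are configuration.

Classes are segmented independently, so per-class segments may overlap;
an `exclusive` mode keeps, per bin, only the class with the largest
smoothed probability. Occupancy runs map back to video time as
`t = bin · duration / 1000`.

## Metrics

* **Sequence-level** (Table-style) metrics are computed on 10-frame
  retained blocks: block probability = renormalized mean of the frame
  rows, block prediction = its argmax, block truth = majority frame label.
  One-vs-rest sensitivity, specificity, and accuracy are reported per
  class; with per-video grouping, point estimates are means over videos
  with a normal-approximation 95% CI, otherwise Wald binomial CIs. Macro
  AUC (rank-based, per class one-vs-rest, classes lacking both outcomes
  flagged NaN) and macro F1 (over classes present in the truth; weighted
  variant available) summarize the multi-class view. Confusion matrices
  are row-normalized percentages over annotated gesture frames, with a
  trailing "none" column when some of those frames were predicted as
  background (so rows still sum to 100).
* **Video-level** agreement uses the 1000-bin timeline. Temporal IoU
  ignores bins where both arrays are 0 and is undefined (0/0) when a class
  is absent from both — the exact situation that *should* count as
  agreement. **Total Agreement** adds matched-zero bins to the
  intersection and union, which makes it algebraically identical to the
  bin-wise agreement rate (TP+TN)/N (proved by exhaustive enumeration in
  the tests) and returns exactly 1.0 for mutually absent classes. The
  (flagged) IoU degenerate case is defined as 1.0 for continuity.
  Stratified summaries report mean ± 1.96·SE per part-procedure, per
  class, and combined; single-observation strata are flagged as having
  degenerate CIs.

## Problem sizes

Default test and benchmark runs are desk-scale by design: the end-to-end
experiment uses 17 surgeons × 3 part-procedures × 2 repetitions of 90-s
videos (102 videos, ~9,200 training sequences) with class separation 3
noise-sd units, which one grouped fold trains in well under a minute on a
single CPU; the near-noiseless recovery check uses 9 surgeons × 1
repetition of 120-s videos. Larger, more realistic sizes (3 repetitions,
~956-s videos) are a parameter change.

## Known limitations

* No pretrained image backbone ships with the package; on real video the
  built-in extractors are weak and an external adapter is expected.
* The Bayes prior construction and all post-processing constants are
  package choices, not community standards; they are exposed as
  configuration and recorded with every CLI run.
* Inference is batch per video; there is no streaming API.
* The synthetic cohort gives every class the same duration distribution
  and every surgeon the same statistics, so it cannot probe class
  imbalance or skill effects unless those knobs are turned explicitly.
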