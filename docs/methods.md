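# Methods

This note documents the models, procedures and numerical choices behind
`fmg_chansel`, and what the synthetic benchmarks do and do not show about
real socket data.

## Data model

A recording is a wide table of raw FSR readings — one row per 10 Hz
sample, one column per channel — with `repetition` (1..5), `gesture`
(six-grip vocabulary: relax, open, force, tripod, point, key) and a
`time_s` column kept as metadata only (no resampling or filtering is ever
applied; raw samples are the classifier inputs).  Validation enforces
finite nonnegative values and that every repetition contains every
gesture.  Channels are addressed 0-based internally; stable string ids
(`s03_c07` = strip 3, cell 7) are the external names reported to users,
because the end product of the analysis is a list of *physical sensors*
to keep.  Gesture labels are case-insensitive on read, and "finger point"
canonicalizes to `point`.

The canonical on-disk format is wide CSV
(`repetition,gesture,time_s,<channel_id>...`, UTF-8, '.' decimal); the
analysis is sample-synchronous across channels, so a long format is not
supported.  Inter-gesture rest periods are assumed already excluded.

## Cross-validation semantics

"LOOCV" in this package always means leave-one-REPETITION-out block
cross-validation.  Samples within a hold are strongly autocorrelated at
10 Hz; per-sample leave-one-out would place near-duplicates of every test
sample in the training set and report meaningless accuracy.  The block
structure (5 folds) is fixed repo-wide.

Two deliberate properties of the evaluation protocol are inherited from
the study design and documented rather than "fixed":

* the final reported accuracy is computed over all five repetitions,
  including the four that served in each fold's selection — an optimistic
  bias;
* the paired t-test compares five per-fold accuracies (df = 4), so its
  power is low and non-rejection is weak evidence.

## Classifier

LDA with pooled within-class covariance, empirical class priors, and a
ridge `reg · trace(S)/d` added to the covariance diagonal
(`reg = 1e-6` by default).  The trace scaling makes the regularizer
unit-free; the ridge guarantees invertibility for duplicated/collinear
channels.  If the pooled within-class covariance is exactly zero
(noise-free synthetic data) but the input is not constant, a scaled
identity replaces it so that distinct class means still classify.
Prediction is the argmax of the Gaussian discriminant score; exact ties
break to the lowest class index (classes ordered by first appearance in
the training labels).  A module-level fit counter audits how many LDA
fits each selection method performs (the filter method must perform
none).

## Selection methods

**mRMR (MIQ).**  Channels are discretized per channel into 3 states
around their own mean (below μ−σ, within, above μ+σ) — a standard scheme
for quotient-criterion mRMR on continuous inputs; n-quantile binning is
available as an alternative.  Mutual information is the plug-in estimate
in bits; the MIQ quotient is scale-invariant, so the log base cannot
affect the ranking (asserted by test against a nats-based oracle).  The
greedy ranking runs to completion; the pipeline then applies the
global-maximum sweep.  Redundancy terms are computed lazily and cached —
only pairs involving selected channels are ever needed.  If a candidate's
mean redundancy is exactly 0, its quotient is treated as +∞ and such
candidates are ordered by relevance; all ties break to the lower channel
index.

**SFS.**  Standard greedy forward selection with the
leave-one-repetition-out LDA error over the training repetitions as the
objective.  Stopping rules: (a) *RII* — stop when
`oldCrit − newCrit < (|oldCrit| + √eps)·TolFun` with `eps = 2.2204e-16`,
`TolFun = 1e-6`, strictly; improvement exactly at the threshold
continues.  The published formula admits a second literal reading with a
leading `oldCrit` factor (a quadratic threshold); this is exposed behind
a `quadratic` flag but not the default, and neither reading is asserted
to be the original intent.  The empty-set criterion is initialized to
1.0.  (b) *global maximum* — rank all channels, then keep the
accuracy-maximizing prefix (ties → smallest prefix).

**GA.**  The named operators (arithmetic crossover, uniform mutation)
are real-vector operators, so the genome is real-coded in `[0,1]^n` with
a 0.5 inclusion threshold rather than a bitstring.  Fitness is the
leave-one-repetition-out LDA error of the decoded subset; an empty
decode scores worst-possible fitness 1.0, keeping the search total.
Generational loop: elitism (2), tournament selection (size 4, default),
whole-genome arithmetic crossover `child = λp1 + (1−λ)p2` with scalar
`λ ~ U(0,1)`, per-gene uniform mutation at rate `1/n_channels` (default).
Termination: mean best-fitness improvement over the last 50 generations
below `1e-6`, backed by a hard 200-generation cap.  Population size and
mutation rate are package defaults (not prescribed anywhere), both
configurable.  Fitness is memoized per decoded subset, which makes
small-instance runs nearly exhaustive at negligible cost.  Because the
GA is stochastic it is repeated (10 restarts by default, seeds spawned
deterministically) and subset sizes are reported as mean ± sd.

**Boruta.**  Importance backend: bagged scikit-learn decision trees with
bootstrap handled in-package, so each tree's out-of-bag sample is
explicit; per-tree importance is the OOB accuracy drop under column
permutation, and the z-score is mean/sd across trees (z = 0 where
sd = 0).  Mean-decrease-impurity is offered as a faster backend with the
caveat that its z-scores differ.  Each Boruta run appends independently
column-shuffled shadow copies (padded to ≥ 5 shadows for very small
channel counts); a channel scores a hit when its z beats the best
shadow's.  Decisions use a two-sided binomial test (p₀ = 0.5) with
Bonferroni correction over the channels still undecided, at α = 0.01 (the
convention of the reference implementation; the study itself fixed only
trees = 500 and runs ≤ 100).  Channels undecided at the run cap are
*tentative* and excluded from selection by default (a flag includes
them).  The subset handed to the pipeline is the global-max prefix of the
final mean-z ranking, not the confirmed set alone.  Run count is
data-dependent and always reported.

## Pipeline conventions

* Per-fold subsets are intersected; an empty intersection raises a
  diagnostic by default, and `fallback_k = N` keeps channels selected in
  ≥ N of the folds instead.
* `Variation%` is ambiguous about its denominator; we use the subset from
  the **larger** training set as reference A, so the statistic reads
  "what fraction of the better-informed selection was lost", and both
  subset sizes are logged.
* The half-data analysis keeps the first half of every
  (repetition, gesture) hold — halving whole repetitions would delete
  entire gesture classes from the tail of each block — and re-scores the
  previously selected subsets without re-selection.
* The hardest gesture per method is the one with the lowest per-class
  recall in the fold-summed confusion matrix.
* Selection runtime is wall-clock of the selection phase only, reported
  but never asserted (hardware-dependent).
* Reports serialize to JSON (machine) and Markdown tables (human); the
  JSON is byte-deterministic under a fixed master seed once runtimes are
  excluded.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Informative channels** carry additive per-gesture mean shifts
  `μ(g,c) ~ N(0, gesture_effect_sd)` — FMG is pressure-pattern based, and
  per-sample classification needs no within-hold dynamics.
* **Redundant channels** mix a source channel's centred pre-clip signal
  with orthogonal noise scaled to the source's empirical sd, pinning the
  channel–source correlation near ρ (default 0.85).
* **Irrelevant channels** carry baseline, repetition offsets and noise
  only.
* **Repetition offsets** `N(0, rep_offset_sd)` per repetition × channel
  model socket re-seating between repetitions; they are the dominant
  reason block-CV accuracy stays below 100 %.
* **Dynamic protocol** adds a common-mode sinusoid (circular arm motion)
  scaled per channel by a random loading in U(0.4, 1.6), making drift
  partially confoundable with gesture patterns.
* **Saturation**: values clip to [0, 25] arbitrary force units; defaults
  keep clipping below ~1 % of samples.

Hold durations are uniform in 15–25 s at 10 Hz, six grips, five
repetitions.  Presets `static63`, `dynamic58`, `dynamic37` reproduce the
three study sensor layouts.  Default effect/offset/noise scales
(`gesture_effect_sd = 1.0`, `rep_offset_sd = 1.4`, `noise_sd = 0.6`) were
calibrated once so preset baselines land in the 70–90 % block-CV band
typical of socket FMG (measured means over four seeds: ≈ 88 %, 90 %,
75 %); the 37-channel preset uses a larger informative fraction (18/37)
because with few channels the repetition offsets otherwise dominate.
One observation from that calibration: LDA projects out the rank-one
common-mode drift almost entirely, so dynamic difficulty is governed by
the offset/effect ratio, not the drift amplitude.

No distributional facts about real FSR socket signals are claimed: all
generator distributions are stand-ins.  Passing recovery tests shows the
pipeline's machinery is sound under the planted model — additive
effects, Gaussian noise, stationary holds — not that any method will
behave identically on real recordings, which add skin-motion artifacts,
nonstationarity within holds, sensor hysteresis and cross-talk.

### Planted-recovery benchmark

`planted_benchmark()` (40 channels, 8 informative, none redundant) is the
package's standard validation instance.  Its conditions are chosen so
recovery is well-posed: gesture effects comparable to sensor noise
(`gesture_effect_sd = 1.0`, `noise_sd = 1.5`) mean no small subset
saturates accuracy and each informative channel adds a measurable
increment, and small repetition offsets (`rep_offset_sd = 0.3`) keep
inner-CV estimates stable.  With strong effects instead, three channels
reach 100 % accuracy and any accuracy-maximizing criterion *correctly*
stops early — recovery of all planted channels would be the wrong
expectation.  Holds are shortened to 2.5–3.5 s for speed; per-sample
structure is unchanged.

## Problem sizes used in validation

The test-suite and acceptance-script runs use reduced scales chosen as
their problem sizes: short holds (2–5 s instead of 15–25 s), 100-tree
Boruta forests with the impurity backend inside the full pipeline
(permutation importance is exercised at 100 trees in the dedicated
Boruta checks), and a GA at population 24–30 with stall window 10–15 on
small instances, where fitness memoization makes the search nearly
exhaustive.  Full-scale defaults (500 trees, population 50, stall 50,
15–25 s holds) remain the library defaults.

## Known limitations

* Sensor *placement* is not optimized — the package reports which
  recorded channels to keep, nothing about where unrecorded sensors
  should go, and no spatial-proximity prior is applied.
* No noise-reduction preprocessing, no feature extraction, no
  classifiers beyond LDA.
* The stability statistic confounds sensitivity to training-set *size*
  with repetition-to-repetition variability; with only five repetitions
  the two cannot be separated.
* Synthetic calibration targets a plausible accuracy band, not any
  specific recording; absolute accuracies on real data are out of scope.
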