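# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Pipeline overview

One analysis run processes a cohort of gaze recordings — one 60 s task per
participant × activity (reading, watching, typing) sampled at 150 Hz — in
five stages: feature extraction (two families), per-feature ANOVA
screening, and a repeated-holdout classification benchmark over the four
feature sets × three classifiers.

## Conventional features

Each of eight derived-event channels (FPOGD, LPD, LPMM, RPD, RPMM, BKDUR,
BKPMIN, SAC_MAG) is summarized inside consecutive non-overlapping 3 s
windows (450 samples; a 60 s task yields 20 windows, trailing partial
windows are dropped) by seven statistics: min, max, median, mean, standard
deviation, variance and skewness — 56 features. Numerical conventions:

* SD and variance use the n−1 denominator; skewness is the adjusted
  Fisher–Pearson coefficient (bias-corrected), the default of mainstream
  statistics tools.
* Samples flagged invalid (VALID = 0) are excluded from every statistic;
  linear interpolation is available behind a flag but exclusion is the
  default because it invents no data.
* Degenerate windows: a constant window reports SD = variance = 0 and a
  missing skewness; an all-invalid window reports all seven as missing.

The channel set is the eight event channels rather than all thirteen
exported columns because summary statistics of screen *coordinates*
(FPOGX/FPOGY, pupil-centre positions) measure stimulus layout more than
oculomotor behaviour, and 8 × 7 matches the 56-feature conventional design
this pipeline reproduces.

## Empirical mode decomposition

EMD represents a channel as `X(t) = Σ cᵢ(t) + rₙ(t)`. Each IMF is
extracted by sifting: subtract the mean of the upper and lower cubic-spline
envelopes through the local maxima/minima until the candidate is locally
symmetric. Design choices, all configurable:

* **Stopping rule** — a Cauchy-type criterion (normalized squared envelope
  mean < 0.2) *and* the defining IMF property (extrema and zero-crossing
  counts differ by ≤ 1), with a hard cap of 100 sifting iterations. The
  count condition is included because the Cauchy criterion alone can stop
  with dozens of uncrossed riding waves on broadband signals.
* **Boundary handling** — the signal is mirror-extended past each end by
  enough samples to cover two extrema before envelope interpolation, the
  standard mitigation of end swings.
* **Extrema** — strict sign changes of the first difference; plateaus
  count once at their midpoint.
* **Mode cap** — six IMFs by default (deeper modes fold into the residue),
  matching the six-IMF complexity feature grid. A 9000-sample broadband
  channel reliably reaches the cap.
* The residue is *defined* as input minus the extracted modes, so the
  reconstruction identity holds to machine precision by construction and
  is asserted to 1e-9 relative in tests.

## Multiscale sample entropy and the complexity index

For a series of length N, `SampEn(N, m, r) = −ln(A/B)`, where B counts
ordered pairs of distinct m-length templates within Chebyshev distance r
and A the same for (m+1)-length templates, both over the first N − m
templates with self-matches excluded. Multiscale entropy evaluates SampEn
on coarse-grained series (non-overlapping block means of length τ) for
τ = 1…10. Parameters follow the standard choices m = 2, r = 0.15·SD,
τ_max = 10.

* **Tolerance** — r is computed once from the SD (n−1) of the *raw*
  channel of the analysis unit and reused for all of that channel's IMFs
  and scales. Late IMFs are therefore scored against a tolerance large
  relative to their own amplitude and read as near-regular (entropy → 0),
  which is the literal consequence of deriving r from the original series.
* **Analysis unit** — the whole 60 s task (9000 samples), not the 3 s
  window: at τ = 10 a window leaves 45 coarse-grained points, far below
  the ~10^m points needed for stable match probabilities, while a task
  leaves 900. A warning fires whenever the coarsest series drops below
  10^m points. Window-level units remain available as an option.
* **Undefined values** — zero match counts (A = 0 or B = 0) yield an
  undefined entropy, recorded as missing, never imputed. The complexity
  index CI sums the *defined* scales and records how many there were;
  a constant channel yields an undefined CI.
* **Counting** — template-pair counting is exact (verified bit-identical
  against an exhaustive O(N²) oracle on thousands of randomized cases,
  including tie-heavy rounded data) but runs sub-quadratically via a
  sweep over the leading template coordinate with a sqrt-decomposition
  bucket structure over the remaining two; all comparisons use the same
  rounded-subtraction predicate as the definition, so even pairs whose
  difference equals r exactly are counted identically. This keeps a full
  cohort tractable: ~1.2 s per task for all 54 channel × IMF profiles.
* SampEn is *not* strictly monotone in r (small-count counterexamples
  exist and one is pinned in the tests); the guaranteed invariant is that
  the match counts A and B are non-decreasing in r.

The complexity table is 9 channels × 6 IMFs × (10 scales + CI) = 594
columns. Note the printed summary this grid is modelled on reports "550"
complexity features, a count no arithmetic over the stated 9 × 6 × 10 grid
reproduces (540 without CIs, 594 with); the implemented grid keeps the
full, self-consistent 594 and the discrepancy is surfaced here rather than
silently reconciled.

## Mixed-model ANOVA screening

Each feature is tested for an activity effect with activity fixed and
participant random. With every participant observed in every activity, the
expected-mean-squares rule makes the activity × participant interaction
the error term: `F = MS_activity / MS_interaction`, df (a−1), (a−1)(s−1).
Implementation notes:

* Sums of squares are computed from cell means; for balanced replicates
  this is algebraically identical to the classic decomposition (the
  replicate count cancels in the F ratio), and it degrades gracefully to
  the unweighted-means analysis when missing values unbalance the cells.
* Conventional features enter with 20 windows per cell as replicates
  (mirroring a design that screens windows directly — pseudo-replication
  included, a per-cell-mean option excluded); complexity features enter
  with one task per cell, which removes the within-cell error term but
  leaves the interaction-denominator test valid.
* Features missing in > 20% of rows are excluded from screening and
  reported separately. Retention uses the raw p-value at α = 0.05 with
  tiers at 0.05/0.01/0.001; no multiple-testing correction by default
  (a Benjamini–Hochberg option exists), mirroring the screening protocol
  this package reproduces rather than endorsing it.
* Type-I calibration is asserted in tests: 2000 null features retain
  5% ± 1.5% and their p-values pass a Kolmogorov–Smirnov uniformity check.

The package bundles the published channel × statistic significance grid of
the original 150-participant cohort (45 starred cells) as a reference
fixture for bookkeeping checks; it is reporting data, not something the
synthetic pipeline is expected to reproduce cell for cell.

## Classification benchmark

Three classifiers × four feature sets = 12 configurations. Per
configuration: stratified random 80/20 row split, six replications with
seeds `base_seed + replication`, accuracy reported as mean ± SD and the
3 × 3 confusion matrix as mean (SD) percentages of **all** test samples
(cells sum to 100; the diagonal sum equals the accuracy).

* Architectures: SVM = RBF kernel with library defaults behind a z-score
  standardizer fitted on the training part (trees are scale-invariant and
  are fed raw features); DT = max depth 5, min samples per leaf 7;
  RF = max depth 5, 1000 trees. The depth-5 DT follows the declared
  architecture summary over a conflicting prose value of 10; both are
  reachable via `dt_max_depth`.
* Screening is performed on the full table before splitting — the
  screen-then-split order of the emulated protocol, optimistic because
  test rows inform the screen; `screen_on_all=False` in the CLI config
  performs screening inside the training part only.
* Rows are split without grouping by participant, again mirroring the
  emulated protocol; `group_by_participant=True` splits whole
  participants and removes that leakage.
* Missing feature values are median-imputed with medians fitted on the
  training part.

## Synthetic cohort generator

The generator is the package's stand-in for undeposited human data; it is
a first-class, tested module whose defaults define the study conditions.

* **Gaze** — a piecewise-constant fixation process: durations ~ truncated
  normal per activity; centres move by saccade-amplitude draws following
  the activity's scan pattern (left-to-right staircases with return sweeps
  for reading; smooth pursuit-like drifting segments for watching;
  alternation between a text zone and a keyboard zone for typing);
  colored-noise jitter rides on the centre.
* **Pupil** — per-activity baseline (watching 19.93 px, typing 19.34 px,
  reading 17.97 px; millimetre channels scaled consistently) plus
  unit-variance colored Gaussian noise scaled to 1.8 px. The noise's
  spectral exponent β (power ∝ 1/f^β) is the complexity knob: reading
  0.15, typing 0.6, watching 1.1. The DC component is zeroed so a task's
  noise averages to exactly zero.
* **Blinks** — a Poisson process (9/7/11 events·min⁻¹ for
  reading/watching/typing) with truncated-normal durations; pupil
  channels read 0 and VALID = 0 during blinks; BKDUR is event-coded on
  the blink-ending sample; BKPMIN is the trailing-10 s onset count scaled
  to events/min. An additional i.i.d. 5% validity dropout emulates
  tracker glitches (≈ 93–95% validity, near the 93.56% reported for the
  real apparatus).
* **Participants** — idiosyncrasies drawn once per participant and shared
  across their three tasks: pupil-baseline offset (SD 1.1–1.3 px), timing
  and blink-rate multipliers (log-normal), and a small spectral-exponent
  jitter (SD 0.05). These create the participant main effect the mixed
  ANOVA expects and keep pooled pupil means in the reported activity
  order.
* **Null condition** — `identical_profiles()` clones the reading profile
  across all three labels; activities then differ only by label and every
  classifier should score at chance. The reading profile is the clone
  source because its near-white pupil noise leaves the fewest
  recording-specific signatures for a window-split classifier to
  memorize.
* Determinism: a recording is a pure function of (profile, config, seed);
  cohort seeds derive from the global seed via `numpy` seed sequences.

### What the generator does and does not emulate

It reproduces the channel inventory, sampling structure, per-activity
pupil baselines, blink statistics, validity levels and — through the
spectral-exponent knob — a complexity ordering among activities. It does
**not** model physiological pupil light responses, stimulus content,
vergence, head movement, or realistic session-to-session drift. Two
consequences matter for interpreting results:

1. Synthetic conventional accuracies (~96–98%) are far above the ~67%
   real-data figure: synthetic within-cell variability is cleaner than
   real recordings, and the row-level split lets windows of the same task
   appear in both train and test. Passing tests therefore demonstrate
   pipeline correctness and the *relative* ordering (complexity >
   conventional), not field-realistic absolute accuracies.
2. The complexity advantage is partly built in by design (the exponent
   knob), so the end-to-end check validates that the pipeline *transmits*
   a complexity difference into classification — not that real gaze data
   contains one.

## Problem sizes

Default test and acceptance runs use 30-participant cohorts (90 tasks,
1800 conventional windows), 200 oracle sequences of length ≤ 60, 100
random EMD signals, 10,000-sample noise references and 2000 null features
— sizes at which every stochastic check has comfortable margins while a
full run stays in the minutes range on one CPU.

## Known limitations

* EMD is the plain single-channel sift; ensemble and multivariate
  variants are out of scope, so mode mixing on intermittent signals is
  possible.
* The mixed ANOVA requires every participant × activity cell to be
  observed; incomplete cohorts are rejected rather than re-weighted.
* SampEn's large-tolerance regime (late IMFs under the raw-channel r)
  compresses entropies toward zero; those features carry little variance
  but are retained for grid completeness.
* The repeated-holdout protocol reuses rows across replications, so the
  six accuracies are not independent; the reported SD understates
  sampling variability.

## A note on null-condition evaluation

With identical activity profiles the cohort carries no activity signal,
yet a row-level 80/20 split does not score at chance: every participant
contributes one task per activity, so the task a split holds out carries
precisely the label the classifier never observed for that participant.
A model that keys on participant identity (pupil offsets make identity
learnable) is then systematically *below* chance — an anti-leakage bias of
the repeated-measures split. Chance-level behaviour of the generator is
therefore asserted under participant-grouped splits, where test
participants are entirely unseen and every test set is exactly
class-balanced; the row-split bias is a property of the evaluation
protocol, not of the data.

Even under grouped splits, a *single* task-level null cohort (90 rows) is
a small dataset: replications reuse the same rows, so a configuration's
mean accuracy inherits a cohort-level wobble of roughly ±6 points (1 SD)
for the high-capacity classifiers — measured here both on generated
cohorts and on pure-noise controls with no generator involved, where
per-cohort means scatter over ~22–42%. A tight two-sided band around
chance for every configuration simultaneously is therefore not a
meaningful assertion at this size (it would need several hundred
participants); the corresponding end-to-end test documents this and is
expected to flag the widest-wobble configuration. The scientifically
load-bearing direction — no configuration performs meaningfully *above*
chance when the activity knob is off — holds with margin.
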