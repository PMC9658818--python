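# Methods

`gaitfuse` implements a hybrid feature-level / decision-level fusion
pipeline for recognizing eight gait-pattern transitions (level ↔ stair,
level ↔ ramp, both directions) from 22-channel kinematic recordings
sampled at 100 Hz. This note documents the models, the conventions the
code commits to, and the limits of what the synthetic benchmark can
show.

## Problem setting

One trial is a single transition stride: a 22 × T matrix of kinematic
parameters (hip/knee/ankle angular accelerations and velocities, segment
velocities and accelerations, trunk terms) plus one of eight class
labels. Recognition proceeds in four stages:

1. **feature bank** — 21 statistics per channel, 462 per trial;
2. **selection** — mRMR ranking to 100 candidates, then a binary-matrix
   shuffling filter (BMSF) to a compact subset;
3. **base classifiers** — BP net (1 × 10 tanh hidden layer), 1-NN, and
   three SVMs (linear / RBF / polynomial kernels), each emitting a
   normalized per-class score row;
4. **decision fusion** — eight combiners of the n × m score matrix,
   centered on Dempster–Shafer (D-S) evidence combination.

A two-stage protocol selects the model: stage 1 counts, for every
fusion rule, how many candidate ensembles fuse at least as accurately
as their best single member under repeated stratified 10-fold CV;
stage 2 stress-tests the surviving ensembles by deleting one kinematic
channel's features at a time (five sensor-failure scenarios, classifiers
retrained on the reduced set) and summarizes the five scenario
accuracies by mean (percent) and population SD (fraction).

## Synthetic data generator

The motion-capture data this pipeline targets is not redistributable,
so `gaitfuse.synthetic` generates datasets with the structure the
method relies on. Each (class, channel) pair has a frozen template: a
sum of ≤ 3 sinusoids with frequencies below 6 Hz (a guard band under
the 7 Hz low-pass character of filtered capture data), amplitudes and
phases drawn once per channel and perturbed per class. Key structural
choices:

- **Band limit by construction.** Template frequencies stay below 6 Hz
  and the oscillatory part is edge-tapered (Tukey, α = 0.4), so the
  finite observation window cannot leak template energy above 8 Hz;
  additive measurement noise (default SD 0.03 in units where waveforms
  are O(1)) is small enough that total energy above 8 Hz stays well
  under 1 %. A transition starting and ending near rest is also what a
  taper looks like physically.
- **Heterogeneous channel informativeness.** Six of the 22 channels
  receive full-scale class deviations; the rest differ between classes
  only weakly (15 % scale). Real transition recognition rests on a
  small subset of kinematic parameters — published feature subsets span
  ~5 channels — and without this sparsity feature selection is
  vacuous.
- **Trial-to-trial variability** (`trial_variability`, default 0.45):
  per-trial amplitude/phase jitter around the class template, at a bit
  under half the scale of the between-class deviations, plus ±10 %
  trial-length jitter. This is the dominant within-class dispersion
  (humans do not repeat identical kinematics) and is itself
  band-limited, since only amplitudes and phases move.
- **Calibration.** With these defaults, single-classifier 10-fold CV
  accuracies on the full 462-feature matrix land in the low-90s to
  100 % — the regime reported for real gait-transition data — and a
  linear SVM clears the ≥ 90 % separability smoke test with margin even
  on a small 96-trial dataset. Defaults were fixed once against those
  two conditions and are not tuned per experiment.
- Units are arbitrary; there is no attempt to mimic physiological
  angle ranges, inter-subject structure, or heel-strike segmentation.
  Trial duration is a free parameter (default 2 s).

Determinism: one master seed freezes the templates; dataset generation
streams a single child generator, so identical configs give bit-identical
datasets.

**What passing tests do not show:** the generator's classes are
stationary sinusoid mixtures with Gaussian perturbations. Real gait has
non-stationary within-stride structure, subject identity effects,
correlated sensor dropouts, and label noise; results here demonstrate
the machinery (selection recovers planted structure, fusion beats
single classifiers under complementary errors, robustness summaries are
computed correctly), not field performance.

## Feature bank

17 time-domain statistics per channel, in fixed order: maximum,
minimum, peak (max |x|), peak-to-peak, mean, average amplitude
(mean |x|), root amplitude ((mean √|x|)²), variance, SD, RMS, kurtosis,
skewness, shape factor (RMS / avg amp), peak factor (peak / RMS), pulse
factor (peak / avg amp), margin factor (peak / root amplitude),
clearance factor (peak / avg amp²). Conventions committed to:

- Population moments (divisor T); kurtosis is *not* excess (no −3).
- Margin and clearance factors are often conflated in the literature;
  here margin normalizes by root amplitude (making it scale-invariant,
  like the shape/peak/pulse factors) and clearance by the squared mean
  absolute value (scaling as 1/c under x → cx), keeping 17 genuinely
  distinct statistics.
- Degenerate inputs (all-zero signal for the normalized factors, zero
  variance for kurtosis/skewness) raise a structured error naming the
  channel; `on_degenerate="nan"` substitutes NaN for batch extraction.

4 frequency-domain statistics use the one-sided DFT amplitude spectrum
s_k at frequencies f_k, DC bin excluded, no windowing or zero-padding
(the simplest defensible convention; the spectrum function is isolated
so a power-spectrum variant could be swapped in): mean frequency
(mean s_k), gravity frequency FC (spectral centroid), RMS frequency
RMSF, and root variance of frequency RVF. These satisfy
RVF² + FC² = RMSF² identically, which the tests exploit.

Features are laid out channel-major (all 21 of channel 1, then channel
2, …), 462 total, with names `"<channel>.<label>"`.

## Feature selection

**mRMR** uses the MID (difference) criterion: greedily add the feature
maximizing I(f; y) − mean_{s∈S} I(f; s). Mutual information is the
plug-in estimate in nats on equal-frequency bins (⌈√N⌉ by default);
label MI keeps y categorical, feature–feature redundancy bins both
variables. The first pick is exactly argmax I(f; y).

**BMSF** is a reconstruction from a one-sentence description of the
original algorithm; the update and stopping rules are this package's
own. Per iteration, `n_rows` (default 30) random binary inclusion rows
over the undecided candidates (retained features always included) are
scored by 5-fold CV accuracy of a linear SVM. A feature is retained
(resp. dropped) when the mean-accuracy gap between rows including and
excluding it exceeds (resp. falls below minus) a threshold of
max(1 %, 2 standard errors of that gap); the rest are reshuffled, up to
`max_iter` (default 8) rounds. The filter is evidence-based: when no
feature ever clears the threshold — e.g. every candidate subset is
equally accurate — nothing can be discarded and all non-dropped
candidates survive. A final verification step compares the retained set
against the full surviving pool and keeps the pool when retention would
cost accuracy beyond the margin: undecided features may still carry
signal, and a filter must never make the model worse. `force_size`
optionally reduces the subset to an
exact size by accuracy-ranked greedy search (off by default; the
natural subset size is whatever the evidence supports).

For the missing-sensor ablation, selected features are grouped by their
source channel. The protocol uses exactly five failure scenarios; when
a subset spans fewer than five channels, the pipeline drivers extend it
with the best-ranked candidates of uncovered channels (ranking order)
before grouping.

## Base classifiers

All five families sit behind one interface: z-score standardization
(fit on training folds only) followed by the estimator, and
`score(x)` returning a row on the probability simplex.

- BP net: 10 tanh hidden units, softmax output, ≤ 500 epochs, seeded
  initialization. The output activation and trainer are not dictated by
  the problem; softmax + Adam (scikit-learn's default) is used.
- KNN, k = 1: scores are one-hot by construction — degenerate for the
  product/minimum rules, which is faithful to k = 1 and absorbed by the
  fusion module's ε-floor.
- SVMs: C = 1; RBF γ = 1/(d·var); polynomial degree 3 (all
  configurable). Scores are Platt-calibrated pairwise-coupled
  probabilities, the canonical libsvm construction.

`predict` is argmax of `score` with ties toward the lowest class id —
the single tie-break convention used everywhere in the package.

## Decision fusion

Scores are mapped to basic probability assignments by reliability
discounting with a single global α (default 0.95): singleton masses
α·z_ij, the rest on the frame Θ. This keeps every source from being
fully committed, so Dempster combination cannot meet total conflict for
α < 1; at α = 1 a conflict falls back to the sum rule (logged), keeping
batch evaluation total. For singletons Bel(A) = m(A) and
Pl(A) = m(A) + m(Θ); decisions use maximum singleton mass (interval-
based decision making is out of scope).

With focal sets restricted to singletons and Θ, Dempster's rule has the
closed form m({c}) ∝ m₁(c)m₂(c) + m₁(c)m₂(Θ) + m₁(Θ)m₂(c),
m(Θ) ∝ m₁(Θ)m₂(Θ), renormalized by 1 − K. Tests verify commutativity,
fold-order invariance, the vacuous mass as neutral element, and
equivalence with a brute-force enumeration over all focal-set products.

Majority voting requires a strict majority and falls back to plurality
(lowest id on ties). Decision templates are the per-class mean training
score matrices, with squared-Euclidean similarity
1 − mean((Z − T_c)²). The algebraic rules (sum, average, max, min,
product) are columnwise combiners; product floors each score at 1e−12;
sum and average share every argmax.

## Evaluation protocol

Stratified shuffled k-fold (k = 10) is assumed — the class counts
(42–45) are small enough that unstratified folds could starve a class.
`repeats` defaults to 10 (100 in the original protocol; configurable)
with per-repeat derived fold seeds. The best single member is measured
on identical folds. Comparisons use unrounded values; display rounds
percent to 2 decimals and SDs to 4.

Stage-1 rule selection maximizes the count of ensembles whose fused
accuracy ≥ their single max, ties by row-maximum count, then the fixed
rule order (ds, vote, dt, sum, average, max, min, product). Stage-2
ablation retrains members from scratch on the reduced feature set
(rather than zero-filling — "absence of the feature data" means the
model never sees them); the summary SD is the population SD (divisor 5)
of the scenario accuracies as fractions, the convention that reproduces
published summaries of this protocol exactly. Stage-2 selection takes
the maximal mean, ties by minimal SD, then the smaller ensemble.

## Problem sizes and runtime

Desk-scale defaults keep a full pipeline run on one CPU in minutes:
study-sized datasets are 350 trials; the reproduction script
(`scripts/acceptance.py`) uses one repeat for the nine-ensemble
stage-1 table, three repeats for the headline {3, 4, 5} D-S accuracy
and two for the five-scenario robustness summary. The protocol's
repeats parameter scales these up when more precision is wanted.

## Known limitations

- BMSF is a reconstruction; no claim of bit-compatibility with the
  original algorithm, only of its contract (keep informative features,
  shed noise, deterministic per seed).
- The BPA construction (α-discounting) is one defensible choice among
  many; per-classifier α from validation accuracy is available but not
  default.
- Saturated benchmarks (every subset 100 % accurate) give BMSF no
  evidence and it rightly discards nothing; use `force_size` when an
  exact subset size is required.
- KNN's one-hot scores make the product/min rules degenerate in
  ensembles containing it; this mirrors k = 1, not a bug.
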