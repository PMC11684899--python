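# Methods

## Model and procedure

The package addresses model selection in multi-objective (MO) wrapper
feature selection, where the quantity being optimized — a
cross-validated fitness estimate — is also the quantity being reported,
and is therefore inflated for the solutions that win the search. The
dual-stage wrapper treats that inflation (overestimation) as a
learnable function of three solution meta-features: the original
fitness, its standard deviation, and the number of selected features.

All objectives are maximized fitnesses in [0, 1]. Natural minimization
quantities are pre-mapped; panel size enters as *root-leanness*
`max(0, 1 − sqrt(k / cap))`, a parsimony score that falls steeply for
the first few features and reaches 0 at the cap. Model-metric
objectives are balanced accuracy (mean per-class recall) for
classification and Harrell's concordance index for survival, both
computed on the pooled out-of-fold predictions of an inner k-fold CV
(pooling is more stable than averaging per-fold metrics on folds of
10–20 samples). The SD of the fitness is a bootstrap SD over the
(prediction, truth) pairs of the inner CV — B resamples drawn with
replacement, the metric recomputed per resample, undefined resamples
(e.g. a class absent) redrawn up to 10·B times. This estimates the
sampling variability of the metric without refitting any model, which
keeps per-candidate evaluation affordable inside a GA.

### Step 1 — collecting overestimation samples

`create_folds` partitions the training samples into `k_outer` folds,
stratified by class (classification) or by the event indicator
(survival); if a stratum has fewer than k members the split falls back
to a plain shuffled partition with a warning. On each fold's training
part the *tuning* optimizer (the same GA at half population and half
generations — a budget-limiting choice, since step 1 multiplies the
search cost by `k_outer`) produces a front; each front solution is then
refit on the whole fold-training part and scored on the fold's left-out
samples. The overestimation of a solution for an objective is its
original (inner-CV) fitness minus this left-out fitness; it can be
negative.

### Sample weighting by hypervolume derivatives

Solutions are not equally important: a solution in a crowded or
dominated region of the front barely influences what a decision maker
sees. Each sample is therefore weighted by `∂HV/∂x_ij`, the partial
derivative of the hypervolume of the fold's front (reference point at
the origin, valid because all fitnesses live in [0, 1]) with respect to
that solution and objective, then scaled to sum to 1 within each
(fold, objective).

The derivative is computed exactly: entry (i, j) is the
(m−1)-dimensional measure of the part of box i's face at height `x_ij`
not covered by any other box, obtained as the face measure minus the
hypervolume of the competitors' boxes clipped to the face. At tied
coordinates the *right* partial derivative is used (the exclusive-slice
measure), which is always well defined; dominated rows and exact
duplicates of an earlier row get zero rows, the kept representative
(lowest index) takes the whole derivative. If an entire gradient column
is zero the weights fall back to uniform. The hypervolume itself is
computed by sorting in 2-D and by dimension-sweep slicing for m = 3–4;
this targets desk-scale fronts (n up to a few hundred, m ≤ 4) and makes
no attempt at many-objective efficiency.

### Step 2 — the adjusters

One regression model per objective maps (fitness, SD, size) →
overestimation, trained with the weights above and minimizing absolute
error where the model family allows it (an HV perturbation is
approximately linear in small fitness errors, so L1 is the natural
loss). Implemented kinds:

| kind | model | notes |
|---|---|---|
| `zero` | constant 0 | the unadjusted optimizer |
| `dummy` | weighted median | exact minimizer of weighted L1; ties resolved to the lowest value |
| `ptree` | absolute-error decision tree, depth ≤ 8 | cost-complexity pruning strength chosen by weighted 5-fold CV of the MAE |
| `rfreg` | random forest, 500 trees, absolute-error splits, `min_samples_leaf=5` | leaf floor keeps the L1 criterion affordable and smooths tiny-sample fits |
| `svr` | RBF ε-SVR, C=1, ε=0.01, standardized inputs | |
| `rsvr` | as `svr`, C and ε by random search (30 draws, log-uniform C ∈ [1e−2, 1e3], ε ∈ [1e−3, 1e−1]) minimizing weighted MAE under 5-fold CV | |

These hyperparameters are this package's own concrete choices; every
kind is a named, swappable factory. The weighted median is implemented
as the smallest value at which the cumulative weight reaches half the
total, which is deterministic and is verified against brute-force L1
minimization in the tests.

### Step 3 — adjusted optimization

Each objective is wrapped into a pipeline that computes the base
fitness, SD and feature count, predicts the overestimation, and reports
`clip(fitness − prediction, 0, 1)`; the SD reported is the base SD.
Clipping is required because the HV machinery demands [0, 1]. The main
optimizer then runs on *all* training samples with the adjusted
objectives, so no samples are sacrificed to produce honest estimates.
With the `zero` adjuster the adjusted pipeline is the identity and the
whole dual-stage run is exactly (bitwise) the bare GA under the same
seed — a tested invariant.

## The reference GA

The wrapped optimizer is pluggable behind a single
`optimize(objectives, data) → solution set` contract; the bundled
reference is an NSGA-II-style GA over binary feature masks:

- initialization: each individual activates `s ~ Uniform{1..init_max}`
  random features (default `init_max_features=10`, biasing the search
  toward small panels);
- variation: uniform crossover with probability `crossover_rate`
  (default 0.9), then a specialized mutation in which each active
  feature deactivates with probability `α/|s|` and each inactive one
  activates with probability `α/(p−|s|)` — in expectation α removals
  and α additions per offspring regardless of panel size (default
  α = 1);
- clone handling: an offspring identical to any current mask is
  re-mutated up to `clone_retry_budget` times (default 3), then
  dropped; an all-empty mask gets one forced random feature;
- survivor selection: non-dominated sorting with a crowding-distance
  tie-break, deterministic via a lexicographic (distance, index) sort;
- hall of fame: every evaluated mask is cached (also deduplicating
  re-evaluations); the returned set is the non-dominated front of all
  solutions ever explored, with duplicate feature sets collapsed.

Crowding-based NSGA-II selection was chosen over NSGA-III reference
directions because the case-study problems have m ≤ 3 objectives, where
crowding is standard; any faithful NSGA-III variant can be plugged into
the registry. Determinism is promised in serial execution only: a
single PRNG stream drives the GA, per-fold seeds are derived as
`seed + 1 + fold` (kept below 2³¹), and objective evaluations are
seeded with the run seed so that cached and fresh evaluations agree.

## Synthetic data

`generate_classification` draws balanced class labels and a Gaussian
matrix: informative features get class-dependent means spaced
`class_separation` apart (unit within-class SD), all other features are
N(0, noise_sd); an optional exponentiation yields positive,
log-normal-like expression values. `generate_survival` draws standard
normal features and exponential event times with rate
`baseline_hazard · exp(Σ β x)` over the informative features
(β = `effect_size` each), then applies uniform censoring whose range is
calibrated by bisection on the drawn times so the expected censored
fraction hits `censoring_fraction`. A `cohort_seed` draws fresh samples
from the same population (same informative features), for external
validation experiments.

Defaults — 60 samples, 500 features, 3 informative, 2 classes,
separation 1.0, unit noise, 30% censoring — emulate a small discovery
cohort in the regime where wrapper selection measurably overfits: with
these sizes the inner-CV estimates of GA-selected panels exceed
fresh-cohort performance on average (a tested property), which is the
phenomenon the adjusters learn. A separation of 1.0 per informative
feature puts the Bayes-optimal balanced accuracy near 0.8, so neither
ceiling nor chance effects dominate. The generator is a Gaussian
class-shift model by design — exact ground truth, no downloads; it does
not reproduce gene–gene correlation structure, batch effects, count
noise, or class imbalance, so passing tests demonstrate the machinery
and the direction of the adjustment effect, not performance on real
cohorts.

## Evaluation protocol

In `cv` mode the whole dual-stage wrapper is assessed by an outer
evaluation k-fold (default 5): it runs on each training part (its own
`k_outer`-fold step 1 nested inside) and its front is re-scored on the
left-out part, giving per-fold MOPE, Pareto delta, CHV and test HV,
reported per fold and as mean ± SD between folds. In `external` mode it
runs on the full training set and is scored on a held-out cohort. Every
reported number is recomputable from the serialized solution sets (the
`metrics` CLI subcommand does exactly that).

The end-to-end directional test uses the generator defaults
(60 × 500, 3 informative), GA budgets of population 20 / 10 generations
(tuning runs at 10 / 5), `k_outer = 3`, and a 3-fold evaluation CV over
5 generation seeds — sizes chosen so the full comparison of the
unadjusted and median-adjusted optimizers completes in minutes on one
core while still exhibiting the overestimation regime. At this scale
the left-out parts hold ~20 samples, so per-fold test fitness is noisy;
the constant (median) adjuster improves the Pareto delta on average but
not uniformly across seeds, consistent with its role as the weakest
non-trivial adjuster. The tree-based adjusters, which can use the
meta-features, recover known monotone overestimation curves with
held-out Spearman > 0.9 in the parameter-recovery tests.

## Numerical choices and edge cases

- Fitness is validated to [0, 1] at the HV boundary and clipped
  upstream (adjusted objectives, holdout metrics), never inside the HV
  code.
- Pareto delta is exactly 0 for zero solutions or zero objectives, by
  definition.
- The c-index returns 0.5 with a warning when no comparable pair
  exists; ties in risk count 0.5.
- A failed inner-model fit on a fold falls back to majority-class (or
  zero-risk) predictions with a warning, so a degenerate candidate
  panel cannot abort a GA run.
- Bootstrap SD returns 0 with a warning if every resample leaves the
  metric undefined.
- Duplicate fitness rows are collapsed to the lowest index wherever a
  unique representative is needed (fronts, HV derivatives).

## Known limitations

- The cross-function υ defaults to "clipped test value"; the package
  preserves the υ(x, x) = x contract and accepts any replacement, but
  ships no other instantiation.
- The reference GA is a documented stand-in, not a claim of equivalence
  to any specific NSGA-III variant; determinism holds in serial mode
  only.
- HV and its derivatives are exact but not optimized beyond m = 4.
- Adjusters regress each objective independently; joint multi-output
  adjustment is out of scope.
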