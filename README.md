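# dosamo

Overestimation-adjusted multi-objective wrapper feature selection for
omics biomarker discovery.

## The problem

Wrapper feature selection searches over feature subsets (candidate
biomarker panels) by repeatedly training and cross-validating a
predictive model on each candidate. When the search is multi-objective
— e.g. maximize the balanced accuracy of a cancer-subtype classifier
*and* the parsimony of the panel, or the concordance index (c-index) of
a survival model — the optimizer returns a whole Pareto front of
panels, each with an expected performance. Because the front is the
best of thousands of evaluated candidates, those expected performances
are systematically optimistic (the winner's curse): the fitness
measured on new samples is lower than the cross-validated estimate that
got the panel selected.

`dosamo` implements a dual-stage wrapper that *learns* this
overestimation and subtracts it during the final search:

1. **Collect overestimation samples.** Run the wrapped multi-objective
   optimizer (a reference NSGA-II-style genetic algorithm over binary
   feature masks) inside a k-fold CV loop. For every solution on every
   fold's front, record three meta-features — the original (inner-CV)
   fitness, its bootstrap SD, and the panel size — and the observed
   overestimation: original fitness minus the fitness measured on the
   fold's left-out samples.
2. **Train one regression adjuster per objective** on these samples,
   each sample weighted by the partial derivative of the hypervolume
   (HV) of the fold's front with respect to that solution and
   objective, so solutions that actually shape the front count more;
   weights are scaled to sum to 1 within each fold. Available
   regressors: `zero` (no adjustment), `dummy` (weighted median),
   `ptree` (pruned absolute-error tree), `rfreg` (random forest),
   `svr`, `rsvr` (SVR with tuned regularization). Absolute error is
   minimized wherever the model allows it.
3. **Re-run the optimizer on all training data** with each objective
   replaced by its adjusted pipeline: fitness → (fitness, SD, size) →
   predicted overestimation → `clip(fitness − prediction, 0, 1)`.

## Set-level error metrics

With `X` the n×m matrix of expected (train) fitness of a front and `X′`
the fitness measured on new samples, all scores maximized in [0, 1] and
the HV reference point at the origin:

- **MOPE**  `E_υ(X, X′) = |H_ι(X) − H_υ(X, X′)|`, where `H_ι` is the HV
  of the train fitness and `H_υ` the cross hypervolume: the HV of the
  matrix with entries `υ(x_ij, x′_ij)` for a user cross-function `υ`
  with `υ(x, x) = x` (default: take the test value, clipped).
- **Pareto delta**
  `P_Δ(X, X′) = (1/m) Σ_j Σ_i |x_ij − x′_ij| · ∂H_ι/∂x_ij`,
  the HV-derivative-weighted mean absolute train–test discrepancy
  (defined as 0 for zero solutions or zero objectives). Unlike MOPE,
  per-solution errors of opposite sign cannot cancel.

The package computes exact HV partial derivatives (the
(m−1)-dimensional exclusive face of each solution's box) for m ≤ 4.

## Worked example

```python
import numpy as np
from dosamo import (
    ClassificationObjective, ParsimonyObjective, DosaMOSelector,
    SyntheticSpec, generate_classification, mope, pareto_delta,
    evaluate_on_holdout,
)

# 60 samples x 500 genes, 3 informative — a small discovery cohort
data, informative = generate_classification(SyntheticSpec(seed=1))
objectives = [ClassificationObjective("nb"), ParsimonyObjective(cap=100)]

est = DosaMOSelector(objectives=objectives, adjuster_kind="dummy",
                     k_outer=3, population_size=20, generations=10,
                     random_state=1)
est.fit(data.X, data.y)
for sol in est.solution_set_.solutions:
    print(sol.feature_set.indices, np.round(sol.original_fitness, 3))
```

prints one line per Pareto-front panel:

```
(181, 293) [0.65  0.859]
(269,) [0.55 0.9 ]
(181, 253, 296) [0.717 0.827]
```

i.e. a 3-gene panel (containing true informative gene 181) with an
*adjusted* expected balanced accuracy of 0.717 and root-leanness 0.827,
down to a 1-gene panel at 0.550 / 0.900 — the expected accuracies
already have the predicted winner's-curse inflation subtracted.
Scoring the front on fresh samples from the same population and
comparing:

```python
holdout, _ = generate_classification(
    SyntheticSpec(n_samples=200, seed=1, cohort_seed=99))
X = est.solution_set_.fitness_matrix()
Xp = evaluate_on_holdout(est.solution_set_, data, holdout, objectives)
print(round(mope(X, Xp), 4), round(pareto_delta(X, Xp), 4))
```

```
0.0597 0.0298
```

A command-line interface mirrors the library:
`dosamo generate` (synthetic datasets), `dosamo run --config cfg.yaml`
(compare adjusters under evaluation CV or external validation),
`dosamo metrics front.json` (recompute MOPE/Pareto delta/CHV from saved
fronts) and `dosamo adjusters export` (dump the overestimation
regression samples as CSV).

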