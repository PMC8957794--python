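# Methods

## Objective surface

The selection objective is `Fit = β·ER + (1−β)·|SF|/|AF|` with β = 0.99.
`ER` is the mean test-fold error of a k-nearest-neighbour classifier
(k = 5, Euclidean distance on the selected columns only) under stratified
5-fold cross-validation. The folds are drawn **once per optimizer run**
from a fold seed and reused for every fitness call, so within a run the
objective is a deterministic function of the mask; re-splitting per call
would turn the objective stochastic and destroy trace monotonicity in a
misleading way. Reporting folds (used by the evaluation panel) are drawn
from an independent seed, so the optimizer cannot be scored on the folds
it optimised against.

Conventions for degenerate cases, all deterministic:

* an empty mask receives fitness 1.0 (worst possible), repelling
  optimizers from the trivial subset; the binarizer additionally repairs
  all-zero positions by promoting the single largest component;
* KNN distance ties are broken by lowest training-sample index (stable
  sort); vote ties go to the class whose nearest representative among the
  k neighbours appears first in that order;
* stratified folding deals each class round-robin across folds, so fold
  sizes and per-class counts differ by at most one; classes smaller than
  the fold count degrade gracefully with a warning rather than failing.

The internal KNN is implemented directly (distance matrix + stable
argsort) precisely so those tie-breaks are specified; the evaluation
panel uses the scikit-learn estimators, giving two independent KNN
routes.

## Optimizers

Agents live in the continuous unit cube; a component strictly greater
than 0.5 selects its feature. Threshold binarization is the simplest
mapping consistent with the observed behaviour of the algorithms (the
slime-mould rule shrinks positions toward 0 and yields very small
subsets; the pathfinder rule keeps positions spread and yields subsets
near half the feature space). The threshold is configurable.

Update rules follow each algorithm's original publication; constants the
originals leave free are exposed with the recommended values:

* **SMA** (slime mould): ranked-fitness weights with a log-scaled
  ratio between the iteration's best and worst fitness; oscillation
  coefficients `vb ∈ [−a, a]`, `a = arctanh(1 − t/T)`, and `vc ∈ [−b, b]`
  with `b` shrinking linearly to 0; random-restart probability
  `z = 0.03`.
* **PFA** (pathfinder): the incumbent best moves by momentum toward its
  previous displacement plus noise decaying as `exp(−2t/T)`; followers
  are attracted to a uniformly chosen companion and to the pathfinder
  with coefficients `α, β ∈ [1, 2]`, plus a perturbation scaled by the
  companion distance and `(1 − t/T)`. The companion choice is uniform
  over the other agents (the original's "interacting member" is not fully
  specified).
* **HGSO** (Henry gas solubility): agents are partitioned into 5 gas
  clusters as contiguous equal blocks, fixed for the run; Henry
  coefficients (init scale 5·10⁻²) decay under the exponential
  temperature schedule with per-cluster rates (scale 10⁻²); solubility
  (pressure scale 10²) scales attraction to the global best and a
  fitness-ratio factor scales attraction to the cluster best; each
  iteration a fraction of the worst agents, drawn uniformly in
  [0.1, 0.2] of the population, is reinitialised. The worst-agent ranking
  uses the previous iteration's fitnesses so the framework keeps a single
  evaluation point per iteration.
* **PSO**: inertia decaying linearly 0.9 → 0.4, cognitive and social
  coefficients of 2, velocities clamped to ±0.6 on the unit cube.

Framework-level elitism retains the best mask ever seen outside the
population, making the best-so-far trace monotone non-increasing for any
update rule. All stochastic draws in a run come from one seeded
generator in a fixed order, so identical configurations reproduce
identical runs byte for byte. Fitness values are memoised per mask
(threshold binarization makes repeats common), which typically cuts
evaluations several-fold.

Defaults are 10 agents and 100 iterations. Population size is a design
choice (the selection behaviour is insensitive to it in our tests);
convergence on the matrices targeted here typically completes within the
first 10–25 iterations, so 100 leaves ample headroom.

## Ensemble combination

Two or three masks over the same feature space are combined into all
pairwise and triple intersections and unions — eight combination subsets
from three inputs. Empty intersections are retained and flagged rather
than dropped: disjoint selections are themselves a finding, and rate
tables render them as "—", excluding them from column averages. Rates
are exact rational arithmetic on mask counts, rounded to 4 decimals only
for display; inclusion–exclusion (`rate(A∪B) = rate(A) + rate(B) −
rate(A∩B)`) therefore holds exactly before rounding.

## Comparison statistics

The Wilcoxon signed-rank test drops zero differences, assigns average
ranks to tied absolute differences, and reports `min(R+, R−)` with a
two-sided p-value. For up to 25 nonzero pairs the p-value is exact,
computed by convolving the sign-assignment null distribution (ranks are
doubled so tied half-ranks become integers); beyond that a normal
approximation with tie-corrected variance and a 0.5 continuity
correction is used. The Friedman test ranks methods within each block
and uses the tie-corrected general chi-squared form with `df = k − 1`
(no F-distribution refinement).

Best-classifier selection counts, over every algorithm × dataset cell,
how often each classifier attains the cell's maximum accuracy, crediting
all tied classifiers. Algorithms are then ranked by the number of
datasets they win under that classifier; ties are broken by smaller
average selected-feature count, then lexicographically.

## Classifier panel

The five evaluation families are concretised as: RBF-kernel soft-margin
SVM (default regularisation), KNN (k = 5), linear discriminant analysis,
a bagged decision-tree ensemble of 50 seeded learners, and Gaussian naive
Bayes — all scikit-learn estimators with the knobs exposed. Binary
metrics pool test predictions over folds; the positive class defaults to
the lexicographically larger label. AUC uses the rank statistic over
pooled continuous scores (signed decision values for SVM, positive-class
vote fractions or posteriors elsewhere). F1 is defined as 0 when
precision + recall = 0. Multiclass inputs are evaluated by accuracy only.
Folds whose training set collapses to one class are skipped and recorded.

## Synthetic data

The generator emulates the two target data families. Expression-like
matrices draw features from Gaussians with unit noise; informative
features separate the class means by `effect_size` standard deviations
(symmetric offsets). Methylation-like matrices draw from beta
distributions with per-feature baseline means in [0.2, 0.8] and
concentration 20; informative features shift the class mean by
`effect_size` beta standard deviations, clipped away from the bounds so
values stay in (0, 1). Missing entries are placed uniformly at a given
rate. Default desk-scale shapes are 60 × 2,000 (expression) and
60 × 20,000 (methylation) — large enough to exhibit the large-p/small-n
geometry while keeping routine runs to minutes.

What the generator does **not** emulate: batch effects, probe-level
annotation structure, chromosomal correlation blocks, or heavy-tailed
count noise. Passing tests on these data therefore demonstrate the
correctness and convergence behaviour of the machinery, not expected
accuracy on any particular public series.

A known behaviour worth stating plainly: with β = 0.99 the optimum of
the objective is a *minimal* separating subset, not the full planted
set. Aggressively shrinking optimizers (SMA in particular) routinely
reach zero cross-validated error with 2–3 features and therefore recover
only a minority of the planted features, while exploratory optimizers
(PFA, PSO) and HGSO recover most of them. This over-selection by SMA is
inherent to the objective, mirrors its extremely low selection rates on
real methylation panels, and motivates the union ensemble.

## Problem sizes used in the automated checks

The test suite verifies exhaustive-oracle dominance on 20 planted-signal
datasets with 10 features (all 1,023 subsets enumerated; 20 agents, 100
iterations; success = within 5% relative of the true optimum in ≥ 4/5 of
seeded runs, aggregated) and planted-feature recovery on 60 × 2,000
matrices with 5 informative features at effect size 3 (medians over 5
seeds). The acceptance script uses 60 × 2,000 expression-like and
60 × 5,000 methylation-like matrices; these sizes keep a full re-run to
tens of seconds while preserving the dimensional regime the method is
designed for.

## Known limitations

* Only the four bundled update rules are implemented; the registry
  accepts plug-ins but ships no others.
* Multiclass problems are supported through the error-rate/accuracy path
  only (no multiclass AUC).
* No imputation: features carrying missing values are removed outright,
  which is appropriate when they are a tiny fraction of the total.
* Wrapper selection with a fixed fold assignment can overfit the folds;
  the decoupled reporting folds expose, but do not remove, that bias.
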