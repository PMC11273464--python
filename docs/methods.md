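# Methods

## Problem setting and model

A multi-label dataset pairs each sample `x_i` (K features: numeric,
nominal, or ordinal) with one value per label; binary labels carry a
designated "present" class so the assignment can be read as a subset
`Y_i ⊆ L`.  Binary relevance (BR) turns this into q independent
single-target problems `D_{y_j}`, each keeping all N rows and the full
feature block.  The federation is *vertical*: every simulated client owns
the shared feature block plus exactly one target column, so all clients
hold N rows ("client balance") and the number of clients equals q.

Training is one round: each client fits its local REPTree; the server's
aggregation is a label-keyed union with no transformation of the members,
so the global model's prediction for label j is exactly the local model's
prediction.  Privacy is embodied as an interface contract — the only
payload crossing the client boundary is the fitted model (schema, splits,
counts); tests assert that serialized models contain no row-level data.
There is no transport layer, encryption, client sampling, or multi-round
averaging: the aggregation is a single union, not FedAvg.

### Multi-class labels

The strict BR formulation assumes 0/1 targets.  Datasets whose labels are
multi-class (taxonomic family/genus/species; breed/pet categories) are
handled in `per_label` mode: one multi-class tree per label, which
matches evaluation reports that carry one metric row per label rather
than per class.  `strict_binary` mode remains available and is the
default whenever every label is binary (`mode="auto"`).

## The REPTree learner

Growth is greedy top-down information-gain search:

- numeric features: candidate thresholds at midpoints between consecutive
  distinct sorted values; the first maximiser (smallest threshold) wins
  ties;
- nominal features: one multiway split on all declared categories; the
  split is admissible only if every category branch carries at least
  `min_num` instances;
- ordinal features are rank-encoded and offered as numeric split
  candidates by default (`ordinal_as_nominal` switches them to multiway);
- a node becomes a leaf on purity, on the depth cap, when its weight is
  below `2·min_num`, or when no admissible split has positive gain.

Split criterion is plain information gain (not gain ratio).  With missing
values present, a feature's gain is computed over its non-missing rows
and scaled by the fraction present; missing rows are routed to the
heaviest child, both during growth and at prediction time.  This hard
routing is deterministic and simple but is a known divergence from
Weka's fractional-instance weighting — trees learned on data with many
missing values may differ from Weka's.

Reduced-error pruning: a shuffle seeded by `seed` partitions the rows
into `num_folds` parts; fold 0 (⌈n/num_folds⌉ rows) is the hold-out, the
rest grow the tree.  Hold-out rows are routed down and recorded as
per-node `prune_counts`; bottom-up, a subtree is collapsed to a majority
leaf whenever the leaf's hold-out misclassification count is less than
*or equal to* the subtree's (ties prune, preferring the smaller tree).
This guarantees the pruned tree's hold-out error and node count never
exceed the unpruned tree's.  Class counts used for prediction remain the
training counts; the hold-out counts are kept for rendering and
inspection only.

Prediction routes a row to a leaf and returns the leaf's majority class
(ties broken by class declaration order).  `predict_distribution`
normalises the leaf's training counts after adding `initial_count` to
every class; a leaf with zero training weight inherits the nearest
ancestor's distribution.

Defaults mirror the stock REPTree surface: `max_depth=-1` (unlimited),
`min_num=2.0`, `num_folds=3`, `seed=1`, `initial_count=0.0`,
`num_decimal_places=2`, pruning on.  `min_variance_prop` and
`spread_initial_count` are accepted for config fidelity but are inert
because all targets here are categorical; `batchSize`, `debug` and
`doNotCheckCapabilities` are accepted in config files and ignored with a
log notice, as they cannot affect the learned model.

### Leaf annotation

`render_tree` prints leaves as `CLASS (a/b) [c/d]` with `a` = training
instances reaching the leaf and `b` = training misclassifications.  Two
bracket conventions exist in the wild for `[c/d]`; the default
(`bracket="majority"`) reports the hold-out majority-class count and the
remainder, and `bracket="holdout_error"` reports hold-out total and
hold-out misclassifications.  Both are exposed because the intended
semantics of published annotated trees is ambiguous.

## Evaluation

Binary labels use the confusion-matrix formulas
ACC = (TP+TN)/total, PR = TP/(TP+FP), TPR = TP/(TP+FN),
FS = 2TP/(2TP+FP+FN), TNR = TN/(TN+FP), FPR = FP/(FP+TN);
zero-denominator ratios return 0 with a logged warning so reports stay
total.  Multi-class labels report accuracy plus one-vs-rest
precision/recall/F/TNR averaged with class-prevalence weights (the
weighting the field's standard toolkits call "weighted"); classes absent
from the truth carry zero weight.  The same prevalence weighting is used
for multi-class ROC/PRC areas — whether the original reports weighted by
prevalence or macro-averaged over classes is not stated anywhere, so the
choice is documented here rather than inferred.

ROC area uses the rank (Mann–Whitney) formulation with midranks for
ties, identical to the trapezoidal area over the tie-grouped curve.  The
precision–recall area integrates trapezoidally over the descending-score
sweep points with ties grouped, anchored at recall 0 with the first
group's precision (an interpolated PR curve, as Weka draws it, rather
than step-wise average precision).

Cross-validation is stratified per label: each label draws its own
k folds stratified on its own target (a `shared_folds` switch reuses the
first label's folds when strict sample-space alignment is wanted).  Fold
sizes differ by at most one with the first `n mod k` folds larger, and
per-fold class proportions deviate from the global ones by at most one
instance.  Test predictions are pooled over folds before metrics are
computed (micro over folds): pooling is invariant to unequal fold sizes,
and every label's row then summarises exactly N predictions.  Reports
render accuracy in percent at 2 decimals and rates at 3; the `Average`
row is the unweighted mean of the label rows.

### Method comparison

`improvement_over_baselines` reports `proposed − mean(baselines)`; when
the inputs are rates on the 0–1 scale the difference is reported in
percentage points.  The Mann–Whitney U test uses midranks, exact
enumeration of all C(n+m, n) group assignments when n+m ≤ 12 with no
ties (two-sided p = probability of a U at least as far from nm/2 as
observed), and otherwise the normal approximation with tie and
continuity corrections.  The Quade test follows Conover's formulation:
within-block ranks weighted by the rank of the block range,
F = (b−1)B/(A−B) on (k−1, (b−1)(k−1)) degrees of freedom; an all-equal
table is a degenerate-input error, and a perfectly ordered table (A = B)
returns the permutation bound 1/(k!)^(b−1).  The implementation was
verified against R's `stats::quade.test` during development; the frozen
values live in the test suite.

## Synthetic data

The generator emulates the *shapes* of the three study datasets —
an amphibian habitat survey (189 samples; ID + motorway metadata columns,
3 numeric, 2 ordinal and 9 nominal inputs, 7 binary presence labels), an
anuran-call MFCC table (7195 samples, 22 numeric features in [−1, 1],
labels with 4/8/10 classes), and a pet-adoption registry (18 834 samples,
mixed inputs, labels with 3/4 classes) — not their marginal statistics or
any acoustic structure.  Features are drawn independently: numeric
uniform over the declared range (floored for integer-valued features),
nominal uniform over categories.

Each label's noiseless value comes from a planted axis-aligned rule of at
most `rule_depth` levels built from single-feature tests: numeric
thresholds drawn from the central 30–70 % of the feature range, nominal
category-membership tests, and contiguous prefix cuts for ordinal
features (so a single rank threshold expresses the test).  A feature is
tested at most once per path.  Leaf classes are a shuffled cyclic draw
from the label's class inventory, so a depth-d rule realises
min(2^d, c) distinct classes — labels with more classes than reachable
leaves (e.g. 10 classes at depth 3) declare the full inventory but
realise only part of it.  Candidate rules are redrawn (up to 500 times)
until, after collapsing pure subtrees, every internal test carries at
least 0.12 bits of population information gain under the uniform feature
marginals.  This rejection step excludes parity-like rules whose top
split carries no marginal signal; without it, greedy information-gain
search cannot recover the rule and recovery would not be a sharp
property of the learner.

Label noise replaces a label value uniformly at random over its class
inventory with probability `label_noise` (so the observed disagreement
with the rule is `label_noise·(c−1)/c`).  The missing mask is applied to
input features only, after labelling.  All draws come from numpy's
seeded PCG64 generator, so a config and seed reproduce the dataset bit
for bit across platforms.

Because features are independent and rules are exactly representable,
passing recovery tests shows the pipeline can learn what it can express;
it says nothing about correlated features, class imbalance, or label
dependencies in real surveys.

## Problem sizes used in checks

Rule-recovery checks run the three presets at N = 2000 with 10-fold
cross-validation (per-label accuracy ≥ 95 % with noiseless depth-3
rules).  The noise-monotonicity check compares mean per-label CV accuracy
at noise 0 and 0.3 over 5 replicate seeds at a reduced size (amphibian
shape, N = 800, k = 5), which is ample to see the large expected
degradation.  These sizes are the package's own choices for fast,
repeatable checks; the generator defaults keep the full preset sample
counts.

## Known limitations

- No exact bit-compatibility with Weka's REPTree is claimed: missing
  values are hard-routed rather than fractionally weighted, thresholds
  are not backfit, and the pruning fold layout is an explicit seeded
  shuffle rather than Weka's internal one.
- Nominal splits are always multiway over the declared categories; an
  unobserved category at a node blocks the split (every branch must meet
  `min_num`).
- The zero-denominator → 0 convention slightly depresses averaged
  metrics for labels with empty prediction classes.
- BR ignores label correlations by construction; classifier chains and
  ensemble variants are out of scope.
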