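# Methods

This note documents the models and procedures implemented in `shapcompare`,
the parameter choices that matter, and what the synthetic test system can
and cannot show.

## Study design

The package reproduces an explanation-consistency protocol at desk scale:
balanced binary activity datasets are built, four classifier families are
trained over independent stratified shuffle-split trials, each model's test
predictions are explained with at least two Shapley-value routes, and the
resulting attribution distributions are characterized and compared with a
statistics suite plus a remove-and-retrain (ROAR) evaluation. All stages are
deterministic given the master seed: every stage, model, trial and instance
derives its own 31-bit seed from the master seed through
`numpy.random.SeedSequence`.

## Synthetic fingerprint generator

The generator emulates a curated compound classification set: two classes of
identical cardinality represented by sparse binary vectors (the data
contract of folded ECFP4 fingerprints). A seeded subset of `n_informative`
bit positions is planted as class-discriminative: those bits fire with
probability `p_on_active` (default 0.8) in actives and `p_on_inactive`
(default 0.1) in inactives, all remaining bits with `p_on_background`
(default 0.05) in both classes. Label noise, when requested, flips labels
*after* bit generation, so the planted bits stay tied to the pre-noise
class and parameter-recovery tests keep their ground truth. Defaults are
desk scale — 256 bits, 20 planted, 100 compounds per class — chosen so that
exact-enumeration comparisons and ROAR retraining run in minutes on one
core; 2048 bits are available through the config.

What the generator does **not** emulate: correlated bit patterns arising
from overlapping atom environments, scaffold/series structure, activity
cliffs, or the heavy-tailed bit-frequency distribution of real fingerprint
corpora. Bits are conditionally independent given the class. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
independent planted signal — not performance characteristics on real
chemistry, where feature dependence is exactly the regime in which the
marginal value function (below) is least defensible.

Background decoy bit statistics are a free parameter of the generator, not a
calibration to any database.

## Record curation

`curate` applies the standard bioactivity cleanup as generic record filters,
in a fixed order: molecular mass ≤ 1000 Da; activity comment not in the
excluded set (inactive / inconclusive / not active / potential author or
transcription errors); measurement type in {Ki, Kd, IC50}; relation exactly
`"="`; potency inside [0.01 nM, 10000 nM] (10 pM–10 µM, held internally in
nM — unit conversion is the reader's job); target relationship type `"D"`
(direct single-protein assay); confidence score exactly 9. A record survives
iff it passes every filter, so the survivor set is order-independent; the
audit attributes each rejection to the *first* failing filter, and records
with missing required fields are counted under `malformed`. Duplicate
compound–target measurements keep the first occurrence (an assumption — the
protocol does not specify aggregation — and logged as such). External
interference/undesired-target filters are out of scope. Balanced sets are
built by pairing the actives with an equal-size seeded uniform sample from a
disjoint decoy pool.

## Classifiers and evaluation

Trials are 10 independent stratified 90/10 shuffle-splits (test sets may
overlap across trials; this is not K-fold). Hyperparameters are selected per
trial by grid search on the training split with an inner 10-fold stratified
90/10 shuffle-split scored by F1, ties resolved to the first grid point for
reproducibility, and the winner refit on the whole training split. The full
grids are: RFC — min samples per leaf {1, 2, 5, 10}, min samples per split
{2, 3, 5, 10}, trees {25, 50, 100, 200, 400}; SVM_RBF — C {0.001, 0.005,
0.01, 0.05, 0.1, 0.5, 1, 10, 100, 10000}, γ {0.0001 … 100}; SVM_TAN — the
same C grid; FFNN — initial learning rate {0.01, 0.001, 0.0001}. Desk-scale
pipeline runs default to fixed single-point grids (`grid_mode="fast"`)
because on planted-signal data the selection problem is trivial and the
search dominates runtime; `grid_mode="paper"` restores the full grids.

The FFNN is a single 256-unit ReLU hidden layer trained with Adam,
batch size 16, log-loss, at most 400 epochs, early-stopped after 20 epochs
without ≥ 1e−4 improvement on a 10% validation split (scikit-learn
`MLPClassifier`); a sigmoid output probability is assumed. The Tanimoto
kernel is K = c/(a+b−c) on on-bit counts, with the 0/0 case of two all-zero
rows defined as 1 (the self-similarity limit), which keeps kernel matrices
positive semi-definite on degenerate fixtures.

Performance is reported as confusion counts plus precision, recall,
balanced accuracy, F1 and MCC computed from the counts (active = positive).
Ratios with zero denominators are reported as 0.

The scalar f(x) that attributions explain is configurable per model:
probability-of-active for RFC and FFNN, the signed decision value for the
SVMs (whose margin lives on a log-odds-like scale), with a logit option.
The choice changes the *scale* of attributions, which is why correlations
and rank-based statistics carry the comparisons.

## Value function and exact Shapley values

Coalition values use the **marginal expectation**: v(S) averages the model
output over background rows whose coordinates in S are overwritten with the
instance's values. This matches the interventional/marginal convention of
the SHAP family, assumes feature independence, and guarantees
v(full) = f(x) and v(∅) = mean background output for any background. The
conditional expectation is out of scope. The background is a seeded random
sample of at most 100 training rows (default 32 in pipeline runs) — the
convention fixes the estimator, not the size, so the size is a cost knob.

`exact_shapley` enumerates all 2^M coalitions (vectorized in one model
call), applies the factorial weights computed in exact integer arithmetic,
and is capped at M = 16. It satisfies efficiency to ~1e−15 and the symmetry
and dummy axioms exactly; a feature identical in the instance and all
background rows receives φ = 0 exactly, because its coalition membership
never changes a composite row.

## KernelSHAP

Attributions solve the weighted least-squares problem over coalition
indicator rows z with Shapley-kernel weights π(s) = (M−1)/(C(M,s)·s·(M−s)),
subject to Σφ = f(x) − v(∅). The constraint is eliminated by substituting
the last coefficient, which enforces efficiency exactly; no regularization
is applied, so with all 2^M − 2 proper coalitions enumerated the solution
coincides with exact Shapley values (observed deviations ~1e−15, tested
against the enumerator on all four model families).

With a finite budget `n_samples` (minimum 2·M), coalitions are chosen the
standard way: complementary size pairs (s, M−s) are enumerated *completely*
in order of decreasing kernel mass for as long as the full pair fits in the
remaining budget, carrying their exact kernel weights; the remaining budget
is filled with complementary pairs sampled from the leftover sizes in
proportion to the kernel weights, duplicates aggregated, the leftover kernel
mass split over the sampled rows by multiplicity. Pure paired sampling was
considered and rejected: at minimal budgets it produces rank-deficient
designs (duplicate small coalitions), whereas completing the singleton pair
first guarantees a well-posed regression whenever n_samples ≥ 2M, while
keeping the variance reduction of complementary pairs. Rank-deficient
designs raise `SingularDesignError` rather than silently pseudo-inverting.
Additive models are recovered exactly from any well-posed design, and the
mean absolute error against exact values decreases as the budget doubles
(property-tested over 20 seeds).

## The reduced top-M protocol

Exact enumeration cannot cover 256-bit models, so the pipeline compares the
two routes head-to-head on reduced models: features are ranked by the pooled
full-width KernelSHAP attributions, each trial's model is retrained (same
hyperparameters) on the top-M features (default M = 12), and exact
enumeration and fully enumerated KernelSHAP are both run on those reduced
models over the same test instances. This is a deliberate scaled-down
protocol: it validates the approximator where ground truth exists, and the
full-width KernelSHAP run carries the analysis at native width.

## Comparison statistics

- **Cumulative present/absent sums** — per correctly predicted compound, the
  sum of attributions over present (bit = 1) and absent (bit = 0) features,
  tagged by true class; emitted both raw and normalized by the row's total
  absolute attribution, since the raw and relative readings differ and both
  are plot-ready.
- **Gini** — computed on *absolute* attribution values: the rank formula
  G = Σ(2i−n−1)X_i / (nΣX_i) presumes non-negative values and can leave
  [0, 1) on signed input; zeros are removed first (the formula applies to
  non-zero values only). This is an interpretive choice.
- **Compacity** — with |values| sorted descending, the smallest count m(t)
  whose cumulative sum reaches t of the total, as a percentage of all
  features; thresholds default to 0.1 … 0.9 in steps of 0.1; curves are
  non-decreasing in t by construction.
- **Consistency** — rows normalized by absolute sum, then a per-feature
  standard deviation across the instances where the normalized value is
  non-zero, stratified by class and feature state; the *sample* (n−1) std
  is used (unspecified in the protocol; recorded as a choice); features
  with fewer than two qualifying instances are reported missing; all-zero
  rows are skipped with a warning.
- **Correlation** — Pearson r over pooled (instance, feature) pairs across
  all trials per model, restricted to all/present/absent features;
  zero-variance pools are reported missing rather than coerced.
- **Faithfulness** — Pearson r between attributions and single-bit-flip
  marginal contributions m_i = f(x) − f(x with bit i inverted), the
  binary-representation adaptation of occlusion; undefined below two
  features or at zero variance.
- **Significance** — two-sided Wilcoxon signed-rank per paired family
  member, Holm–Bonferroni step-down across the family, star tiers at
  adjusted p ≤ 5e−2 / 1e−2 / 1e−3 / 1e−4; degenerate pairs (all-zero
  differences) are reported missing and excluded from the family.

Per-instance statistics are restricted to correctly predicted compounds by
default (a config switch includes all), matching the design of explaining
*successful* predictions.

## ROAR

Rows are normalized by absolute sum, each feature's global importance is the
absolute sum of its normalized values across all attributed test instances,
and the ascending order (ties to the lower feature id) is the removal
ranking. At each schedule step the n least important features are *deleted
from the representation* — models are retrained on shorter vectors, not
zero-masked — and test MCC is recorded; seeded uniform random removals of
equal size (5 control seeds by default) form the control. Hyperparameters
selected on the full representation are reused for every retraining step;
re-tuning per step was not done (unspecified in the protocol; this bounds
compute and holds the model class fixed). The 2048-bit schedule is
(100, 1000, 1500, 1700, 1800, 1900, 1950, 2000, 2023, 2038, 2043); the
256-bit desk schedule (25, 128, 192, 224, 240, 248, 251, 253, 254, 255)
mirrors its dense-near-full-removal geometry, and its final step leaves a
single feature (schedules may go that far; only a step removing *all*
features is an error). On planted-signal data the informed trajectory stays
at ceiling until the planted bits start to go, while random removal decays
roughly with the fraction of surviving planted bits — the qualitative
ordering the acceptance check asserts beyond the halfway point.

## Problem sizes

Default analysis runs use the desk-scale generator (256 bits, 20 planted,
100 per class), 10 trials, 512 KernelSHAP coalition samples per instance,
32 background rows, up to 20 attributed test instances per trial, top-12
reduced models, and 5 ROAR control seeds. These sizes were chosen once as a
desk-scale study configuration; full-scale widths (2048 bits, full grids)
are reachable through the config but are not what the tests assert on.

## Known limitations

- The marginal value function ignores feature dependence; on real
  fingerprints (correlated bits) its attributions can leak importance to
  co-occurring features. This is a property of the convention, not a bug.
- Sampled KernelSHAP error depends on the budget; 2M samples is the
  well-posedness floor, not a convergence recommendation.
- The model-specific closed-form Shapley algorithms for SVMs and trees
  (SVETA, SVERAD, TreeSHAP, DeepSHAP) are not implemented; the exact
  enumerator plays the model-specific role at reduced width.
- `consistency`/`correlation` pooling assumes aligned instance sets between
  methods per trial, which the pipeline guarantees but hand-built inputs
  must respect.
- The FFNN is a scikit-learn MLP; probability calibration is whatever the
  log-loss fit yields, uncalibrated.
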