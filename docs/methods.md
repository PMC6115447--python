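# Methods

## The model

`assl` implements a binary lasso-logistic classifier embedded in a combined
self-training / active-learning loop for settings where a gene-expression
cohort of `n = n1 + n2` samples has only `n1` labeled samples and the
remaining `n2` are unlabeled.

The core classifier is

    P(y = 1 | x) = sigmoid(b0 + x . beta),

fit by minimizing the weighted penalized objective

    sum_i w_i * logloss(y_i, b0 + x_i . beta) + lambda * ||beta||_1

with the intercept unpenalized.  Genes with nonzero fitted coefficients are
the "selected" genes; gene-selection performance is scored on that support
(NC = correctly selected, NS = total selected, with gene-level sensitivity
NC/n_true and specificity TN/(TN+FP)).

## The training loop

Six variants share one mechanism.  Each iteration `t = 1..C` of the loop:

1. scores the unlabeled pool with the current model;
2. selects pool samples through two disjoint probability windows that widen
   linearly — the self-training (SSL) window `prob <= gamma_t` or
   `prob >= 1 - gamma_t` for high-confidence samples, and the uncertainty
   (AL) window `0.5 - alpha_t < prob < 0.5 + alpha_t`, with
   `gamma_t = alpha_t = t * SZ / 4` so the windows exactly exhaust (0, 1)
   at `t = C = 1/SZ`;
3. labels the selections (classifier pseudo-labels, or hidden true labels
   from a simulated oracle for the manual baselines, budgeted at 40% of n2)
   and refits;
4. (update mechanism, Auto-ASSL-B only) finds pseudo-labeled samples whose
   predicted class flipped under the refit model: SSL-selected flips return
   to the pool unlabeled, AL-selected flips have their label revised in
   place.

The loop ends at `C` or as soon as the pool empties.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `step_size` (SZ) | 0.1 | per-iteration widening of total window mass; `C = 1/SZ` |
| penalty `lambda` | CV-tuned | lasso penalty; tuned once on the initial labeled set by 5-fold stratified CV maximizing held-out log-likelihood over a 50-point log grid from `lambda_max` down to `1e-3 * lambda_max`, ties to the sparser model |
| `oracle_budget_fraction` | 0.4 | fraction of n2 the manual baselines may have labeled by the oracle, spent closest-to-0.5 first |
| `flip_margin` | 0 | optional confidence dead-zone for flip detection (0 = any boundary crossing flips) |
| `tune_scoring` / `tune_one_se` | `loglik` / off | alternative CV rules (misclassification scoring, one-standard-error rule) that select sparser models |

Two numerical choices matter and are deliberate:

* **Penalty scale across iterations.**  The penalty is held fixed on the
  *mean-loss* scale: when the training set grows from `n1` to `n_t` samples
  the sum-loss penalty becomes `lambda * n_t / n1`.  Holding the sum-loss
  penalty literally constant makes the relative regularization vanish as
  pseudo-labels accumulate; the model then reproduces every training label
  exactly and the update mechanism can never fire.
* **Standardization.**  Genes are standardized to zero weighted mean / unit
  weighted variance on the current training set before solving and
  coefficients are reported on the original scale, so the penalty is
  scale-equivariant; weight-k samples behave exactly like k duplicates.

Solver: scikit-learn's liblinear coordinate descent (`l1_ratio=1`),
`tol = 1e-7` in the loop (1e-8 for standalone fits), coefficients below
1e-8 snapped to exact zero, intercept penalty suppressed by a large
intercept-scaling factor and replaced by its closed form in the
full-shrinkage case.  Fits are deterministic given the data.

Tie rules, all fixed: pseudo-label at prob exactly 0.5 is class 0; a
probability on a shared window boundary goes to the SSL selector; oracle
priority ties at equal |prob - 0.5| go to the lower probability; penalty
ties in CV go to the larger penalty.  Degenerate inputs (one-class training
set, non-finite values, empty grids) raise errors rather than guessing.

## The synthetic benchmark

`simulate_dataset` emulates a two-group high-dimensional study: `p = 4000`
genes, marginally standard normal and equicorrelated at `rho = 0.3` through
one shared per-sample factor (`x_ij = g_ij * sqrt(0.7) + g_i0 * sqrt(0.3)`);
10 causal genes with coefficients `beta_true = 5 * ones(10)`; linear
predictor `eta = x . beta + eps`, `eps ~ N(0, 1)`; labels drawn
`y ~ Bernoulli(sigmoid(eta))`; a uniformly random `n1` of the samples keep
their label (Group A: 100 of 300, Group B: 150 of 450).  The dataset is a
pure function of its config, and hidden truth is retained for the oracle
and for evaluation.

The same-sign coefficient default is load-bearing.  With alternating signs
the shared factor cancels exactly out of `eta`, capping every causal gene's
marginal correlation with the label near 0.2 *independently of the
coefficient scale*; at these sample sizes that is below the noise floor of
4000 genes and no lasso fit recovers anything.  With same-sign coefficients
the shared factor carries most of the signal and the baseline classifier
reaches the high-0.8 accuracy / ~0.93 AUC regime the method comparison
assumes.  The scale 5.0 was calibrated once against that anchor and frozen;
accuracy is insensitive to it over a wide range because the performance
limit is estimation error at `n1 = 100-150, p = 4000`, not label noise.

What the generator does **not** emulate: real microarray noise, batch
effects, block or decaying correlation structure, class imbalance, or
non-Gaussian expression marginals.  Passing tests therefore demonstrate the
mechanics and relative behavior of the training variants under a clean
equicorrelated Gaussian design, not performance on real cohorts.

## Observed behavior of the variants, and limitations

Under these conditions (20 paired replicates, shared data, mask and penalty
per replicate):

* The oracle-assisted baselines (AL-lo, ASSL-lo) reach ~0.95-0.97 unlabeled
  accuracy: uncertainty-sampled true labels are extremely informative.
* The fully self-labeled variants (SSL-lo, Auto-ASSL-A/B) stay at the level
  of the plain logistic baseline (~0.83-0.84).  Pseudo-labels are the
  model's own predictions, so they add no new information; as the windows
  expand, the uncertainty band contributes near-coin-flip labels that
  slightly erode the fit.
* The update mechanism is structurally constrained: with a CV-chosen
  penalty the model has enough capacity to reproduce its own pseudo-labels
  (no flips, B identical to A); with sparser penalties flips do occur but
  the revision rule (align the label with the current model) is
  self-confirming and can destabilize the fit.  Both regimes were mapped;
  the default configuration sits in the stable one.

These are properties of the method under this simulation design.  The
acceptance tests in `tests/test_acceptance.py` assert the comparative
orderings and the >90% headline accuracy that the method is expected to
deliver; the ordering and headline checks fail under this generator —
honestly reflecting that the self-labeled variants do not outperform the
supervised baseline here — while the specificity bands, the window/update
mechanics and the solver oracles pass.  The real-data analyses (DLBCL, prostate, GSE21050,
GSE32603) are out of scope, though the TSV readers accept such matrices.

## Problem sizes

The replicated comparisons use 20 replicates for the Group A six-variant
table, 12 for the Group B headline accuracy, and 20 per group in
`scripts/acceptance.py`; each replicate performs ~250 cross-validation fits
plus up to ~60 loop fits at `p = 4000`, all single-threaded liblinear.
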