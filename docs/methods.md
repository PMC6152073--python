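# Methods

## Model and procedure

`dtirvm` predicts drug–target interactions from protein sequence
information alone. A pair (drug, target) is represented by the target
protein's evolutionary profile descriptor; drugs contribute only their
identity in the bipartite interaction network (a concatenation hook for
drug descriptors exists in `build_pair_dataset`, but no drug featurization
is implemented — the pipeline is deliberately protein-only).

### PSSM normalization

PSI-BLAST ASCII profiles carry integer log-odds scores. Only the first
block of 20 columns is used; the percentage block is ignored. Rows for
nonstandard residues (X/B/Z/U) are kept so the matrix length always equals
the query length. Three normalizations are available:

- `sigmoid` (default): element-wise logistic `1/(1+e^{-s})`, mapping each
  score into (0, 1) so the bi-gram sums behave like products of
  probability-like terms. Chosen as the default because it is the common
  practice in the profile-bi-gram literature and is strictly monotone in
  the raw scores.
- `rowsum`: each row is shifted by its minimum and divided by its sum
  (raw log-odds rows can sum to ≤ 0, so a plain row-normalization is not
  well defined); an all-constant row maps to the uniform 1/20. Provided
  for sensitivity analysis.
- `raw`: identity.

### Bi-gram descriptor

For a normalized profile *P* (L × 20), the descriptor is
`B[m,n] = Σ_{i=1..L−1} P[i,m]·P[i+1,n]`, flattened row-major
(u = 20(m−1)+n, 1-based) into exactly 400 entries. The flattening order is
fixed so feature indices are comparable across implementations. For L = 1
the sum is empty and the vector is zero. The computation is a single
matrix product `P[:-1].T @ P[1:]`; tests verify it against an independent
four-loop oracle to 1e-10 on 50 random profiles.

### PCA

Feature matrices are reduced 400 → 350 by centered PCA
(`sklearn.decomposition.PCA`, full SVD) with a deterministic sign
convention: the largest-magnitude loading of every component is forced
positive, making projections reproducible across linear-algebra backends.
Fitting requires strictly more samples than components. Two placements are
available in cross-validation: `per_fold` (default; fit on the training
fold only, leakage-safe) and `global` (fit once on the pooled data). Both
are exposed because published pipelines often do not state which was used;
neither is asserted as canonical.

### Relevance vector machine

The classifier is the regression-form RVM trained directly on 0/1 labels
(Gaussian likelihood; no logistic link or Laplace approximation), with a
bias column and one kernel basis function per training point:

- design matrix: Φ[i, 0] = 1, Φ[i, j+1] = k(xᵢ, xⱼ);
- posterior: Σ = (σ⁻²ΦᵀΦ + diag(α))⁻¹, u = σ⁻²ΣΦᵀt, solved by Cholesky
  factorization with an escalating diagonal jitter (starting at
  1e-10·trace/m) before declaring failure — poly2 Gram matrices are
  routinely ill-conditioned;
- hyperparameter updates: γᵢ = 1 − αᵢΣᵢᵢ (clipped to [0, 1]),
  αᵢ ← γᵢ/uᵢ², and optionally σ² ← ‖t − Φu‖²/(N − Σγᵢ);
- pruning: basis functions with α above `alpha_prune` (default 1e12) are
  removed each iteration; surviving training inputs are the relevance
  vectors;
- convergence: max |Δ log α| over survivors < `tol` (default 1e-3), cap
  `max_iter` = 1000. On non-convergence a warning is recorded in the model
  metadata and the best state is returned.

Defaults follow the published configuration for this pipeline: kernel
`poly2` = (1 + x·z/width)² with width 1 (the inhomogeneous degree-2
polynomial; the original toolbox's kernel formula is not published, this
is the standard reading), α initialized to 1/N, decision threshold 0.5 on
the continuous score.

**Noise variance.** σ² is initialized to max(0.1·var(t), 1e-3) and, by
default, *not* re-estimated (`TrainingConfig(update_sigma2=False)`). This
is a deliberate design choice: on 0/1 targets the kernel basis can
interpolate the labels, so the residual-based σ² update collapses toward
zero — the classic degenerate maximum-likelihood variance estimate — which
halts pruning (nearly all basis functions retained) and makes the model
memorize the training labels. Empirically, on separable two-Gaussian data
(n = 200), the collapsing update yields ~88% held-out accuracy with 198/200
basis functions retained, while the fixed-σ² variant prunes to a few dozen
relevance vectors and reaches ~97%. The toolbox convention this pipeline
descends from flags "beta" as a classification-mode switch, consistent
with not re-estimating the noise in classification use. The residual
update remains available via `update_sigma2=True` for genuinely noisy
regression targets.

The log marginal likelihood (evidence) of the active basis is recorded at
every iteration; on the test problems it is non-decreasing across accepted
iterations (checked with 1e-6 slack — the fixed-point updates are not
formally guaranteed monotone, but behave so in practice).

### Dataset construction and evaluation

Known interactions form the positive set of a bipartite graph. Negatives
are drawn uniformly **without replacement** from the non-edges, once per
experiment (before splitting, not per fold), with size
round(ratio·|positives|); ratio 1 (the default) balances the classes
exactly. Cross-validation is stratified by label (an unstratified mode
exists). Metrics per fold: Ac = (TP+TN)/total, Sn = TP/(TP+FN),
Pe = TP/(TP+FP), Mcc with the standard four-factor denominator, all as
percentages; a metric with a zero denominator is reported as NaN rather
than 0. Sensitivity is recall — TP/(TP+FN) — which is the only reading
consistent with published benchmark tables of this pipeline family.
Aggregation over folds uses the sample standard deviation (ddof = 1); this
reproduces the reference aggregation 97.73 ± 0.40 from the per-fold
accuracies (97.95, 97.52, 97.26, 98.29, 97.61). ROC/AUC are computed on
the pooled held-out scores via threshold sweep and trapezoidal rule
(`sklearn.metrics.roc_curve`/`auc`), cross-checked in tests against the
Mann–Whitney pairwise-comparison identity.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of (parameters, seed):

- `gen_pssm` — L × 20 i.i.d. uniform integer matrices on [−10, 10],
  matching the magnitude of PSI-BLAST log-odds (so the sigmoid operates in
  a realistic regime) and the file dialect, but **not** the positional
  autocorrelation or compositional structure of real profiles.
- `gen_network` — uniform random bipartite edge sets; defaults (445 drugs,
  664 targets, 2,926 positives) mirror the enzyme benchmark's shape.
  Edges are random, so there is no learnable drug–target signal: an
  end-to-end experiment on simulated networks is a null experiment and
  correctly scores at chance.
- `gen_two_class_features` — two unit-variance Gaussian clouds in feature
  space with Euclidean mean separation `s` (per-coordinate shift
  s/√dim/2). Class structure is injected at the feature level rather than
  by simulating sequence evolution because the classifier consumes
  features, and this gives a controllable effect size. Default separation
  6.0: Bayes error ≈ Φ(−3) ≈ 0.13%, i.e. clearly learnable but far enough
  from trivial that an overfitting classifier is visibly penalized.

Consequently, green tests demonstrate correctness of the computations and
sane behavior of the learning pipeline under known conditions; they do not
certify accuracy on real curated DTI benchmarks, which additionally
require PSI-BLAST profiles against a large database.

## Numerical choices and degenerate inputs

- Posterior solves never form explicit inverses except to return Σ (whose
  diagonal the γ update needs); the system is Cholesky-factorized with up
  to three jitter escalations (×10 each) before raising with the condition
  number.
- α updates with uᵢ = 0 produce α = ∞ and immediate pruning; the active
  set is never allowed to empty (the smallest-α basis function is kept).
- Convergence is checked *before* applying the final α update, so a fit
  with `tol=∞` returns exactly the posterior at the initial α (useful for
  reduction tests).
- Ill-conditioning bounds reproducibility: identical fits are bit-equal,
  but algebraically equivalent evaluations through different BLAS call
  sequences agree only to ~1e-7 on poly2 Grams, and test tolerances
  reflect that.
- `run_cv(pca_components=None)` skips PCA; passing a component count ≥ the
  feature dimension is an error rather than a silent no-op.
- PSSM parsing validates row numbering, column counts and residue letters,
  and reports the offending line; empty files and missing headers are
  explicit parse errors.

## Problem sizes in the test suite

Unit and property tests run on profiles of length ≤ 400 and training sets
of ≤ 200 samples; the end-to-end cross-validation checks use n = 200 pairs
in 20 dimensions (five RVM fits of 160 training points each). These sizes
exercise every code path, including pruning and convergence, with the full
suite completing in a few seconds.

## Known limitations

- No drug featurization: pairs sharing a target are identical in feature
  space, so the model cannot distinguish them. This mirrors the
  protein-only design it implements; the `drug_features` hook allows
  supplying external fingerprints.
- The regression-form RVM yields uncalibrated continuous scores, not
  probabilities; threshold 0.5 is a convention.
- The fast sequential sparse-Bayes algorithm is not implemented; training
  is O(N³) per iteration and practical to a few thousand pairs.
- Negative "non-interactions" are unverified absences, a standard caveat
  of balanced negative sampling on interaction networks.
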