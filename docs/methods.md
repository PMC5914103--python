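# Methods

## Problem setting

Two-class tabular data with a rare "abnormal" (positive) class and an
abundant "normal" (negative) class, as in medical screening.  The cost of
a missed abnormal case dominates, so the quantities of interest are the
abnormal-class recall and the symmetric summaries (g-mean, balanced
accuracy) rather than plain accuracy.  Labels are stored as abnormal = 1,
normal = 0 throughout; "positive" always means abnormal.

## Ensemble of rotation trees

Each of the `M` members is built independently from the training split
`(X_a, X_n)` with `N_a = |X_a| ≤ N_n = |X_n|`:

1. a balanced set `D_i` of `2·N_a` rows: all of `X_a` plus `N_a` normal
   rows drawn uniformly without replacement;
2. a uniform random partition of the `n` features into subsets of size
   `L` (the last subset takes the `n mod L` remainder when `L ∤ n`);
3. per subset, PCA fitted on an object sample of `D_i` (fraction 0.5,
   drawn independently per subset, without replacement by default;
   bootstrap selectable) restricted to that subset's columns, keeping all
   components;
4. the loading blocks assembled into a sparse orthogonal `n × n` matrix
   `R_i` indexed by original feature number;
5. a decision tree trained on `D_i R_i`.

Prediction: each tree votes on `X R_i`; majority vote, ties to abnormal.
The tie direction is a deliberate choice — under equal evidence, the
costlier error is the missed abnormal case.

Defaults `M = 100`, `L = 3`, `fraction = 0.5` are the standard benchmark
configuration for this family of methods.

### PCA details and numerical choices

- **Centering.** The per-subset sample mean is subtracted when *fitting*
  a block, but the rotation applied to data is the pure linear map `X R`
  (no mean shift).  Feature standardisation is off by default.
- **Rank deficiency.** Blocks come from an eigendecomposition of the
  sample covariance; when the covariance is rank-deficient the
  eigenvectors of the null eigenvalues already form an orthonormal
  complement, so every block — and hence every assembled rotation — has
  full rank and `RᵀR = I` holds to 1e−8 (in practice 1e−14).
- **Sign convention.** Each loading column is flipped so its
  largest-magnitude entry is positive (first such entry on ties), making
  results reproducible across numeric backends.
- **Component order.** Columns are sorted by decreasing eigenvalue; exact
  eigenvalue ties keep the decomposition's order, which is deterministic
  for a fixed input.
- **Tiny samples.** The covariance divisor is `max(m−1, 1)`, so a
  single-row sample yields a zero covariance and an identity-like block
  rather than NaNs; sample sizes use a ceiling so a one-row balanced set
  still funds a nonempty PCA sample.

### Diversity combinatorics

The number of distinct unordered partitions of `n` features into
`K = n/L` subsets of size `L` is `T = n!/(K!·(L!)^K)`; the probability
that `M` independently drawn partitions are pairwise distinct is the
birthday-problem product `Π_{i=0}^{M−1}(T−i)/T = T!/((T−M)!·T^M)`,
evaluated with exact rational arithmetic.  For `n = 9`, `L = 3`:
`T = 280` and the 50-member all-distinct probability is ≈ 0.0095 < 0.01,
which is why the method layers object sampling and undersampling on top
of partition randomness.  The closed form is only defined for `L | n`;
the unequal-subset regime is refused rather than approximated.

## Comparison methods

All methods share the `BaseLearnerSpec` contract; the default base
learner is scikit-learn's `DecisionTreeClassifier` with the entropy
criterion, the closest standard stand-in for C4.5's information-gain
trees (unpruned by default).

- **RURF** learns each `R_i` on a balanced undersample exactly as above
  but trains the tree on the rotated *full* training set — the single
  structural difference from the rotation-tree ensemble, kept explicit in
  the code.
- **Bagging**: `M` trees on size-`N` bootstrap resamples, majority vote.
- **AdaBoost.M1**: sample-weight boosting.  Per round with weighted error
  `ε`: stop if `ε = 0` (keep the perfect learner with a large, capped
  vote weight) or `ε ≥ 1/2` (discard the round); otherwise downweight
  correct examples by `β = ε/(1−ε)`, renormalise, and give the member
  vote weight `ln(1/β)`.  If the very first learner is no better than
  chance it is kept alone with weight 1 so prediction never fails.
- **EasyEnsemble**: `T` balanced undersamples, one AdaBoost.M1 of
  `rounds` weak trees per sample (`T = rounds = 10` → 100 trees); the
  final decision sums every weak learner's weighted vote across all
  subensembles and thresholds at half the total weight (ties abnormal).
- **BalanceCascade**: as EasyEnsemble, but after each stage the normal
  examples that the cascade-so-far classifies correctly are removed from
  the sampling pool in decreasing confidence order (lowest abnormal vote
  share first).  Removal never shrinks the pool below `N_a`, so the next
  stage can always be funded; if the pool is exhausted the cascade stops
  early with fewer stages.
- **Single tree**: one tree on the raw training set.

**Weak learner for the boosting-based methods.**  An unpruned tree
reaches zero training error on almost any balanced sample, which stops
AdaBoost.M1 after one round and would silently collapse EasyEnsemble and
BalanceCascade to `T` single trees.  Their default weak learner is
therefore a depth-2 entropy tree (`WEAK_LEARNER`), which keeps all ten
boosting rounds meaningful — the role pruning plays for classic C4.5
weak learners.  Any other spec can be passed explicitly.

## Metrics

From the confusion cells (TA, FN, FA, TN) with abnormal positive:
accuracy, precision `TA/(TA+FA)`, recall `TA/(TA+FN)`, the δ-weighted
f-measure `(1+δ²)·P·R/(δ²R+P)` with δ = 1 by default, g-mean
`√(recall_a · recall_n)`, and the hard-label AUC estimate
`(recall_a + recall_n)/2`.  Degenerate conventions: precision and
f-measure are 0 when their denominators vanish (so ranking never
crashes); g-mean and the AUC estimate raise when a true class is absent,
since they are undefined.  The AUC figure used everywhere is this
balanced-accuracy estimator computed from hard votes; a score-based
trapezoidal ROC AUC exists for diagnostics but is never substituted.

## Evaluation protocol

Ten repetitions of 10-fold cross-validation → 100 (train, test) pairs
per dataset.  Folds are stratified by default; the protocol's verbal
description is plain random folding, but several benchmark datasets have
fewer than 40 abnormal cases and unstratified folds can produce
single-class test sets, so stratification is the safer default
(unstratified mode is available, and when the minority class is smaller
than the fold count the code degrades to plain K-fold with a warning).

Method comparisons use a two-sided paired Student t-test on the 100
paired per-fold scores (df = 99), at α = 0.05, with no correction for
the correlation between folds — matching the benchmark convention this
protocol reproduces; the docstring carries the anticonservativeness
warning.  Zero-variance differences are decided by the mean: all-zero →
not significant, nonzero constant → significant by convention.

Summary tables report mean ± sample standard deviation of the 100
values (the ± magnitudes in tables of this style are SDs, not standard
errors of the mean, and are labelled as such).  Ranks are per-dataset
competition ranks, best = 1.0, ties averaged — so each dataset's ranks
always sum to `m(m+1)/2` — then averaged over datasets.  Recomputing
ranks from the frozen reference tables follows this stated rule even
where the source's own printed averages differ slightly (its 2.4/2.8
recall ranks for EasyEnsemble/BalanceCascade versus 2.56/2.69 under
tie-averaging); the implementation does not chase the printed values.

## Synthetic data

`gen_gaussian` draws both classes from multivariate normals with a
shared covariance (identity, or a random correlation matrix with unit
variances); the abnormal mean is shifted by `separation` within-class
SDs along a random unit direction.  This is the minimal model with a
tunable overlap: separation 0 is the null, ~2 the overlapping-but-
learnable regime used for the simulation checks, 6 near-separable.  The
direction is part of the seeded draw, so `gen_train_test` draws the
geometry once and samples matched train/test sets from the same
population.

`gen_profile` reproduces the *shape* of eight published medical
benchmark datasets — size, imbalance degree (abnormal/total, the
convention consistent with those tables' printed degrees, with the
verbal abnormal/normal ratio selectable), and attribute count (which
includes the class column, hence `attrs − 1` predictive features).

What the generator does **not** emulate: nominal attributes, missing
values, non-Gaussian class shapes, label noise, and within-class
substructure.  Passing simulation tests therefore demonstrate the
mechanics and the direction of the rebalancing effect, not expected
performance on any real dataset.

## Test and simulation sizes

Unit and property tests run on datasets of tens-to-hundreds of rows with
reduced ensemble sizes; the directional simulation uses the full
configuration (`M = 100`, `L = 3`) on 50 abnormal / 500 normal,
9 features, separation 2, over 20 seeds, with matched test sets of the
same size.  These sizes give stable method orderings while keeping the
whole suite fast; all randomness flows from explicit seeds and every
pipeline is bit-reproducible under a fixed seed.

## Known limitations

- Multi-class problems are out of scope by construction (the rotation
  ensemble has no class-subset elimination step; two classes only).
- The t-tests are descriptive, not calibrated inference (fold
  correlation).
- Model files are serialised with joblib/pickle (tree internals are not
  portably text-serialisable); rotation matrices themselves have a
  plain-text rendering via `RotationMatrix.to_text`.
- ARFF support covers the Weka dialect read by `scipy.io.arff`
  (numeric + nominal attributes, `?` missing); date/string attributes
  and KEEL pre-partitioned fold files are not supported.
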