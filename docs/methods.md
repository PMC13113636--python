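# Methods

## Dependence measure

`dcorselect.dcor` implements the V-statistic distance-correlation
estimator for univariate samples: Euclidean (absolute-difference) distance
matrices, double centering, `V²(x,y) = (1/n²) Σ Ã·B̃`, and the normalized
ratio `V²(x,y) / (sqrt(V²(x)·V²(y)) + ε)` with `ε = 1e-10`.  Two
conventions matter:

* **No square root of the ratio.** The quantity reported is the ratio of
  squared distance covariances itself (sometimes written dCor²), which is
  what the selection pipelines rank and weight by.  It lies in [0, 1] and
  is zero iff the numerator is zero.
* **Biased V-statistic.** No U-statistic bias correction is applied.  At
  n = 500 the null estimate for independent normals is small but positive
  (median ≈ 0.004 over 50 replicates in the test suite); the pipelines
  consume only rankings and smooth transforms of the scores, for which the
  bias is immaterial.

Degenerate inputs: a constant vector gives a zero numerator and the score
is defined as 0 (the ε guard exists precisely so this never divides by
zero).  Non-finite inputs are rejected with a `ValidationError`.

dCor is exactly invariant to similarity transforms (affine maps) of either
variable, because univariate distances scale by |a| and the ratio cancels
— up to a deviation of order ε introduced by the non-scaling guard, which
the tests bound at 2e-9.  It is *not* invariant to general monotonic
transformations, and no such property is asserted.

## Kernel feature maps

`dcorselect.kernel` builds explicit Nyström-style RBF maps: centers are
drawn without replacement from training rows with a seeded generator, and
σ is a quantile of the **training sample-to-center** Euclidean distances
(exact zeros excluded first).  This is the distance collection computed
immediately before the bandwidth step in the pipeline order; the
alternative (all pairwise training distances) gives very similar values
but is quadratic in n.  The choice is recorded in each fitted selector's
metadata.  Percentiles interpolate linearly between order statistics.

## Weighting schemes

* **Inverse penalty** `1/(dCor + 0.01)`: moderate-dependence features get
  the larger multiplier (dCor 0.5 → ≈2.0) while near-perfect ones stay at
  ≈1.0, so after weighting, distances in the kernel's input space are
  driven relatively more by complementary moderate features than by a
  redundant high-dependence cluster.  The 0.01 offset caps the weight at
  100 for dCor = 0.
* **Proportional weights** `dCor²`, normalized to mean 1 (ratios
  preserved; 0.9 vs 0.3 scores keep their 9× spread).  This is the
  conventional direction and serves as the ablation contrast.
* **Center importance** `Σ_j dCor_j/(|c_ij| + 0.1)` scores each kernel
  center *after* the transform from its coordinates in the z-scored
  training space; it multiplies kernel-matrix columns.  The formula is a
  heuristic proximity weighting, not derived from a model.

Direction of application: weights multiply feature (or kernel) columns
after fold-local z-scoring.  All top-k rankings break ties by ascending
column index for reproducibility.

## Sparse refinement

All LASSO / elastic-net stages regress the {0,1}-coded label by penalized
least squares, matching the MSE-based λ selection rules (min-CV-MSE and
the conservative 1-SE rule).  The λ grid holds 100 log-spaced values from
the smallest λ that zeroes every coefficient down to 1e-4 of it; the
intercept is handled by centering and no solver-internal standardization
is used (columns are standardized or kernel-bounded upstream).  α is the
L1 fraction of the penalty.  The coordinate-descent solver is
scikit-learn's `enet_path`; the grid construction, CV fold loop, and λ
rules are this package's.  When fewer than k coefficients are nonzero at
the chosen λ, top-k extraction fills remaining slots deterministically by
the same magnitude-then-index ordering.

## Pipelines

Stage orders and hyperparameters per method are listed in
`dcorselect.pipelines` (module docstring).  Points where the design was
genuinely open:

* **Operating space.** Kernel pipelines select kernel *centers* (a
  "feature" is a similarity to a specific training row); the hybrid M8
  selects from the 7 + 100 concatenation.  The uniform contract is
  therefore "select k columns of the method's operating space".
* **Clamping.** The reference center/pre-selection counts (279, 200, 150,
  100 centers; 100/50/30 pre-selected features) assume ≈339 training rows
  and 279 features.  On smaller inputs the pipeline clamps
  `n_centers ≤ n_train` and pre-selection counts ≤ p rather than failing;
  the module-level operations still enforce their preconditions when
  called directly.
* **Pre-selection is integral to M4.** The inverse penalty is applied
  *after* keeping only the top-100 dCor features.  If the table has fewer
  features than the pre-selection size, nothing is discarded and the
  penalty then amplifies near-zero-dCor noise features by up to 100×,
  letting them dominate the kernel metric — M4 can drop to chance on such
  tables.  This is a property of the cascade, not a defect: the benchmark
  in `examples/02` therefore studies the penalty mechanism at the
  feature-selection level (`penalty_weighted_feature_selection`), where
  its redundancy-breaking effect is directly measurable.
* **M2's pre-selection LASSO** uses the plain-LASSO settings (α=1, 5-fold,
  min-MSE); **M4's bandwidth** is the median rule inherited from the
  kernel stage it reuses; **M8's LASSO** uses the defaults (α=1, 5-fold,
  min-MSE).  Per-method seeds are derived from the run seed by fixed
  offsets so each method is independently reproducible within a run.

## Evaluation protocol

Stratified k-fold (default 4) with seeded shuffling; per-fold class counts
are within one of exact proportionality.  Normalization is fold-local
z-scoring with the sample (n−1) standard-deviation convention;
zero-variance columns get σ = 1, and residual non-finite values map to 0.
Training-fold statistics are applied unchanged to the held-out fold.

The classifier is a fixed feed-forward network: hidden layers of 50 and 30
sigmoid units, a 2-unit softmax output trained on one-hot targets with
full-batch gradient descent (batch-summed gradient) at learning rate 0.01
for at most 279 epochs, seeded Gaussian initialization scaled by
1/√fan-in.  It is deliberately simple and identical across methods; all
cross-method conclusions are comparative.

Metrics: accuracy, precision, recall, specificity, F1 at threshold 0.5,
and ROC-AUC as the Mann–Whitney rank statistic with half-credit ties.
Ratios with zero denominators are reported as 0 and flagged.  Accuracy
ranking uses per-fold means; the extended metrics are computed on
predictions pooled across folds — both appear in the report.

Paired comparisons: two-sided paired t-test and the exact two-sided
Wilcoxon signed-rank test (zero differences dropped before ranking; exact
null distribution, no normal approximation).  At n = 4 folds the smallest
attainable Wilcoxon p is 0.125, so non-significance there carries no
information; the report surfaces both p-values so this floor is visible.

## Synthetic benchmark

Defaults (chosen once as a realistic desk-scale analogue of a mixed
biomedical table): n = 500 samples, balanced Bernoulli target, 5 linear
features (unit effect, unit noise), 5 quadratic and 3 sinusoidal features
(class-modulated spread, symmetric about zero so linear correlation ≈ 0),
2 redundant clusters of 5 near-copies (within-cluster r ≈ 0.99), and 30
pure-noise features.  What it does *not* emulate: real ECG feature
marginals (heavy tails, mixed scales, nominal codes), label noise,
class imbalance beyond the balance knob, and cross-family correlation
structure.  Passing recovery tests therefore demonstrates that the
selectors respond to the planted dependence types as designed, not that
any accuracy level transfers to clinical data.

Stochastic tests are majority votes (or means) over ≥ 20 fixed seeds,
never single-run assertions.  Problem sizes in the test suite (n = 120–500,
p ≈ 16–48) were chosen so the full suite exercises every pipeline
end-to-end at desk scale.

## Known limitations

* dCor is computed per feature (univariate screening); no block/multivariate
  distance correlation, and no O(n log n) fast estimator — cost is
  O(p·n²) per fold.
* The filter baselines are faithful textbook implementations (10
  equal-frequency bins for χ²/MI/mRMR, deterministic all-instance ReliefF
  with 10 neighbors and range-normalized differences, MID-variant mRMR,
  forward-greedy CFS); they are not bit-compatible with any particular
  commercial toolbox's internals.
* The LASSO stages are least-squares on a binary label, not penalized
  logistic regression; λ rules and coefficient rankings, not calibrated
  probabilities, are consumed downstream.
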