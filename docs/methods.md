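# Methods

## Data model

A dataset is a samples × features table of real numbers with missing cells
carried as NaN (`OmicsMatrix`). CSV input uses a feature-name header row,
an optional second row of feature-group labels, and a first column of
sample identifiers; empty cells, `NA` and `NaN` (any case) are read as
missing, and missing cells are written back as empty fields. Values are not
required to be positive at load time — positivity is enforced only where
MAPE needs it (non-positive truths are excluded from the error sum, with a
logged count, and an all-excluded holdout raises).

Pre-filtering removes features, then samples, whose percent-missing is
**≥** the user threshold (a row or column exactly at the threshold is
removed; the bound must be fixed somewhere and the closed form makes the
filter idempotent and easy to reason about). Sample percentages are
recomputed on the feature-filtered table, so the two axes compose
deterministically.

## Missingness simulation

All three simulators operate on a complete matrix and return both the
masked matrix and the hidden cells, so imputation error is computable
exactly. Cell budgets are `round(threshold · pool)` with round-half-up; a
budget of zero or of the entire pool raises instead of silently masking
nothing/everything. Every (mechanism, feature-or-sample, group) triple gets
its own RNG stream derived from `SeedSequence([seed, mechanism, index])`,
so masks are reproducible and independent of iteration order.

* **MCAR** draws one uniform(0,1) number per cell and masks the lowest
  `round(threshold · Ns·Nf)` draws — the budget is matrix-wide, which is
  what makes every cell exchangeable.
* **MNAR** works per feature: draw `L1 ~ logistic(0,1)` and
  `L2 ~ uniform(0,1)` of length Ns, form `L3 = L1·L2`, rank `L1`, `L3` and
  the feature's measurements (ordinal ranks, ties to first occurrence),
  pick the `round(threshold · Ns)` most extreme `L3` ranks, and for each
  picked position mask the cell whose measurement rank equals the `L1` rank
  at that position. Extreme products require extreme logistic draws, so
  masked cells concentrate at the feature's value extremes — the
  detection-limit signature. The budget splits `floor(b/2)` cells to the
  high tail and the remainder to the low tail; the extra cell goes low
  because left-censoring is the common case in mass spectrometry.
* **MAR** runs the same construction per sample across features, but ranks
  each cell's *co-dependence score* — the sum of the sample's other feature
  values — rather than the cell's own value. With declared feature groups
  the score is computed within the cell's group, and each (sample, group)
  block is processed independently with budget `round(threshold ·
  group_size)` and its own RNG stream. Ranking jointly across groups would
  let one platform's values move another platform's mask, which would break
  the point of declaring groups; the per-group design makes group masks
  provably invariant to other groups' values (a property the test suite
  checks by permutation). Without groups this reduces to the per-sample
  `round(threshold · Nf)` rule. A group of size 1 has no co-dependence
  partner and raises.

## Imputation methods

Eight methods sit behind one dispatch; with groups declared, each group is
imputed independently. All methods guarantee observed cells are returned
untouched and the output is complete.

* Constant fills: feature minimum, minimum/5 (a crude detection-limit
  surrogate; a minimum of 0 imputes 0), maximum, median (even counts
  average the central pair), mean.
* **kNN**: features are z-scored (observed mean/SD; zero-SD features get
  scale 1), neighbours found by nan-Euclidean distance over mutually
  observed features (sklearn `KNNImputer`), the missing cell filled with
  the unweighted mean of the k nearest samples, and the result scaled
  back. A sample with no co-observed neighbour falls back to the feature
  mean. `k ≥ Ns` raises.
* **Chained random forest** (missForest-style): initialise missing cells
  with feature means, visit features in increasing-missingness order,
  regress each on all others with a forest and overwrite its missing
  cells, and sweep until the imputed values stop changing (relative
  successive change `< 1e-6`, or increasing) or 10 sweeps. The per-feature
  forests are LightGBM's random-forest mode (bagging fraction 0.632 per
  tree, `sqrt(p)` feature subsampling as in ranger, min leaf 2): a forest
  engine with per-tree overhead low enough that the full tree-count grid
  search over {5 … 500} trees remains interactive on one CPU. Columns with
  fewer than two observed values keep their mean fill, and any non-finite
  forest prediction (possible when bagging leaves too few rows on very
  small data) falls back to the current fill.
* **Chained equations**: `n_iter` full sweeps of per-feature Bayesian
  linear regression on all other features with posterior-draw noise
  (sklearn `IterativeImputer` + `BayesianRidge`, `sample_posterior=True`),
  returning a single completed dataset. Predictive mean matching and
  Rubin-rules pooling are out of scope — the artifact's contract is one
  completed matrix.

Defaults: k = 10 neighbours, 500 trees, 2 chained-equation sweeps.

## Method selection

Eligibility requires ≥ 6 samples, ≥ 3 features and ≥ 18 observed values.
The complete submatrix is extracted by a ladder — complete samples;
complete features; after dropping features with ≥ 80 % missing (strict
`< 80 %` retained), complete samples then features of the reduced table —
returning the first rung whose complete submatrix still spans 6 × 3.

Each mechanism is simulated once per run at the threshold (default 0.30;
a `replicates` option averages over additional simulation seeds). Every
method imputes every simulated dataset and is scored by MAPE on the hidden
cells. Simple mode evaluates the multivariate methods at their defaults
(clipping k to Ns−1 on very small subsets, with a warning); full mode
scans k ∈ {10, 30, 50, 70, 90} (the printed 10–100 range is unreachable
past 90 in steps of 20) followed by a refined k\*−4 … k\*+4 pass clipped
to [1, Ns−1], tree counts {5, 10, 20, 50, 100, 150, 200, 500}, and 1–3
chained-equation sweeps, with ties to the smaller value. The same
simulated datasets are reused across the grid — resimulating per grid
point would confound hyperparameter effects with simulation noise.

The reported 8 × 3 table holds, per cell, the best MAPE over the evaluated
grid for that mechanism. The recommendation minimises the arithmetic mean
across the three mechanisms (ties break by method order: MIN, MIN5, MAX,
MEDIAN, MEAN, KNN, RF, MICE); the mean is used because a method dominating
all three mechanisms need not exist, and the full table is reported so
users can apply a different rule. The single hyperparameter retained per
multivariate method is the grid value minimising that pooled mean, since
one value must be chosen to impute the original table. The original matrix
is then imputed with the recommendation.

## Diagnostics

`compare_datasets` contrasts the complete-case deletion of the original
table with the imputed table: pooled histograms of feature-z-scored values
on shared Freedman–Diaconis bin edges (shared edges make the two
distributions directly comparable); per-feature skewness `m₃/m₂^{3/2}` and
kurtosis `m₄/m₂²` as population (biased) moments, kurtosis *not* excess so
a normal feature reads 3 and the attainable minimum is 1; and full-rank
PCA on column-standardised data in both orientations (samples as
observations, and features as observations with samples as variables).
Features with |skewness| > 1 are flagged in the report notes as possibly
MNAR — a soft hint, not a decision rule, since no principled threshold
exists. A degenerate complete-case matrix (< 2 rows or columns) omits PCA
with a note rather than failing.

## Synthetic data

The generator emulates the gross shape of MS feature tables: `n_latent`
shared Gaussian factors, per-feature loadings drawn from ±uniform(0.5,
1.5) (bounded away from zero so each feature is strictly monotone in the
signal when noiseless), feature-specific Gaussian noise of SD `noise_sd`
on the signal scale, and either exponentiation (lognormal-like, skewed
marginals; default) or a positive affine shift (`marginal="linear"`, for
scenarios where features should be linear maps of the factors). Defaults
are 45 samples × 40 features with 3 factors and noise SD 0.25 — the scale
of a small metabolomics study. It does **not** emulate batch effects,
instrument drift, heteroscedastic noise, or real censoring, so passing
tests demonstrate correctness of the machinery, not performance claims on
real cohorts. `golden_matrices()` holds hand-written matrices with known
answers (constant table, duplicated-row kNN case, collinear pair, the
80 %-column ladder case, the 18-value eligibility boundary).

## Numerical and testing notes

Ranks are ordinal with ties to first occurrence — continuous draws make
ties measure-zero but real data tie, and determinism is required for
testing. All stochastic components take an explicit integer seed and named
`SeedSequence` streams; identical inputs and seed give bit-identical
reports. Statistical property tests (MCAR uniformity by chi-square, MNAR
tail enrichment, MAR co-dependence tracking, multivariate-beats-mean) use
seeded Monte-Carlo at small scale — typically 20–500 replicates on
matrices up to 50 × 50 — chosen to keep the full suite comfortably
interactive while leaving the statistics far from their decision
boundaries.

## Limitations

Method selection assumes the complete submatrix is representative of the
full table; when missingness is strongly MNAR the complete subset is a
biased sample and the simulated MAPEs are optimistic. Very small complete
subsets (near the 6 × 3 floor) make multivariate methods unreliable and
may require a lower simulation threshold. Mixture mechanisms and explicit
detection-limit censoring models are out of scope; users with known mixed
missingness can group features by suspected mechanism and impute each
group separately.
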