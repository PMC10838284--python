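# Methods

This note documents the models, algorithms and numerical choices behind
`radbench`, in the order the pipeline uses them.

## The problem being modeled

Radiomic feature tables are small-n, large-d (often more features than
samples), strongly inter-correlated in groups, and frequently
class-imbalanced. Resampling methods are widely used to balance such data
before training, but they act *before* feature selection and can therefore
change which features a filter selector picks — with consequences for both
predictive performance and feature interpretability. The package measures
both effects under a protocol that rules out information leakage from
validation data.

## Preprocessing

Tables are preprocessed by (1) removing named problem features — by default
the two exponential-filter texture features whose values overflow and go
missing in several public datasets — (2) imputing remaining missing cells
with per-feature means, and (3) z-scoring every feature.

Numerical choices:

- **Standard-deviation convention.** Sample sd (n−1 denominator). The
  convention is recorded in `PreprocessorState.sd_ddof` so a run is fully
  reproducible.
- **Zero-variance features** map to all-zero columns rather than being
  dropped, preserving column indexing across folds; the affected columns
  are flagged in `PreprocessorState.zero_sd_mask`.
- **Preprocessing scope.** The default is *global* (whole-table impute +
  z-score before CV), matching how such studies are typically run; the
  harness accepts `preprocess_mode="per_fold"` to refit imputation and
  scaling on training folds only, which is the hygienic alternative. Both
  modes leave resampling, selection and classifier training strictly
  fold-internal.
- **Missing-value markers** in CSV: empty cells plus the common NA/NaN
  tokens.

## Synthetic data generator

`synthdata.generate` emulates the statistical traits of radiomic tables
with a tractable oracle:

- Features come in consecutive **equicorrelated Gaussian blocks**:
  within a block, `x_j = sqrt(ρ)·g + sqrt(1−ρ)·e_j` with independent
  standard normal `g`, `e_j`, so every marginal is N(0,1), every
  within-block pair has correlation exactly ρ, and blocks are independent.
- **Informative features** (default one per block, starting at the block's
  first column) get a mean shift δ added for positive-class rows. Because
  marginals have unit variance, δ is directly a Cohen's d.
- **Class counts are fixed** (not Bernoulli draws) so a generated table
  matches its profile exactly; rows are shuffled so ordering carries no
  label information.
- **Missingness** is MCAR: `round(missing_rate · n · d)` cells chosen
  uniformly without replacement.

Defaults: ρ = 0.8 over blocks of 10 features, δ = 2, missing_rate = 0.
These reflect the strong redundancy reported for radiomic features; the
correlation spectra of the real public datasets are not characterized
anywhere, so ρ and the block size are a modeling choice, not a fit.

Fifteen built-in `DatasetProfile`s span the observed shape range of public
radiomic datasets (n ∈ [51, 922], d ∈ [118, 7106], B ∈ [1.0, 4.0]); the
profile ratios B are checked against the tabulated one-decimal values.

**The oracle.** For k informative features, each shifted by δ in distinct
(hence independent) blocks, the optimal score restricted to those
coordinates is their sum, giving `AUC = Φ(δ√k/√2)`. The full-covariance
Bayes rule is strictly better when ρ > 0 — correlated, unshifted
block-mates can be used to denoise the informative coordinate (for one
informative feature in a 10-block at ρ = 0.8 the Mahalanobis shift grows
from δ to about 2.1·δ). The package deliberately uses the marginal form as
its recovery oracle because it is what a filter-then-classify pipeline can
attain; the recovery acceptance test accordingly uses classifiers (naive
Bayes, kNN) that do not exploit the full covariance.

**What the generator does not emulate:** real radiomic feature families
(GLCM/NGTDM etc. have heavier tails and nonlinear dependencies, not just
linear correlation), batch effects between scanners, and informative
missingness. Tests that pass on this generator therefore demonstrate
algorithmic correctness and the qualitative agreement/similarity
phenomenon, not clinical performance on any real dataset.

## Resampling methods

All nine methods are implemented in this package (no external resampling
library), as pure functions of `(table, spec)`: identical inputs give
bit-identical outputs. Distances are Euclidean on the (z-scored) features;
all nearest-neighbor ties break toward the lower sample index.

- **Random under/over**: uniform removal of majority rows / duplication of
  minority rows until equal counts.
- **SMOTE**: synthetic minority points `x + u(x′ − x)`, `u ~ U(0,1)`, where
  `x′` is drawn uniformly from the seed's k nearest minority neighbors
  (k capped at minority_size − 1). Seeds cycle round-robin over a randomly
  permuted minority list, so each minority point contributes
  ⌊need/m⌋ or ⌈need/m⌉ synthetics — deterministic load balancing. A
  minority class of size 1 falls back to random oversampling with a
  warning.
- **SVM-SMOTE**: seeds are the minority support vectors of an RBF SVM
  (C = 1, γ from the mean-distance heuristic) fitted on the full training
  table. A seed whose 10 nearest overall neighbors are majority-dominated
  interpolates toward a near minority neighbor; otherwise it extrapolates
  outward (`x + u(x − x′)`). No minority support vectors → fall back to
  SMOTE.
- **Edited NN** (k = 3): one pass; a majority sample is removed when the
  strict majority of its k nearest neighbors (any class) carries the other
  label. Only the majority class is edited — the method is used here as an
  undersampler. If the pass would empty the majority class, the
  highest-index candidate survives (with a warning): small minority-heavy
  neighborhoods can otherwise wipe out a class.
- **All k-NN**: the ENN edit iterated for k = 1..k_max on the shrinking
  table, stopping early if an iteration would remove every remaining
  majority sample. `k_max ∈ {3, 5, 7}`.
- **Tomek links**: cross-class mutual-nearest-neighbor pairs; the majority
  member of each link is removed.
- **Combined**: SMOTE first, cleaning second (ENN with k = 3, or Tomek).
  The SMOTE-stage neighborhood grid for SMOTE+ENN defaults to {3, 5} and
  for SMOTE+Tomek to {3, 5, 7}; both configurable.

When class counts are tied, the negative class (0) is treated as the
majority; over/undersamplers are no-ops on balanced input.

## Feature selection

Four filter scorers, each producing one relevance value per feature:

- **ANOVA F** = MS_between / MS_within; a zero-within-variance feature
  with a nonzero shift scores +∞, which sorts above every finite score
  (making the ranking total); zero shift with zero variance scores 0.
- **Bhattacharyya distance** between per-class Gaussians:
  `D = (μ₁−μ₂)²/(4(σ₁²+σ₂²)) + ½ ln[(σ₁²+σ₂²)/(2σ₁σ₂)]`, class variances
  floored at 1e−8.
- **Extra-trees importance**: mean impurity decrease over 250 extremely
  randomized trees (matching the forest classifier's tree count; scores
  sum to 1).
- **L1-logistic coefficients**: absolute coefficients at a single default
  penalty (C = 1), liblinear solver at tolerance 1e−8 (tight enough that
  the solution is effectively unique on well-determined problems). One
  retry with a 5× iteration budget on non-convergence, then a warning.
  Note the usual L1 instability: duplicated informative columns may split
  or concentrate their coefficient mass.

`select_top` keeps the N highest-scoring features, ties broken by
ascending column index; N comes from the logarithmic grid
{1, 2, 4, 8, 16, 32, 64}, capped at d.

## Classifiers

kNN (k ∈ {1,3,5,7,9}), logistic regression and RBF-SVM with
C ∈ {2⁻¹⁰, 2⁻⁸, …, 2⁸, 2¹⁰} (the 11 even powers, including 2⁰), Gaussian
naive Bayes (variance floor 1e−9), and a 250-tree random forest. The
RBF kernel width is γ = 1 / (mean Euclidean distance over all unordered
sample pairs) of the training table — the mean distance itself, not its
square. Scores are positive-class probabilities where available and the
SVM decision function otherwise; AUC is invariant to the difference, and
the sensitivity/specificity threshold adapts (0.5 for probabilities, 0 for
margins).

## Cross-validation protocol

Stratified 5-fold CV with 30 repeats (configurable). Within each fold, the
training rows alone are resampled, scored, reduced to the top-N features,
and used to fit the classifier; validation rows are only transformed and
scored. The leakage property is tested directly: flipping every
validation-fold label changes no selected feature set and no validation
score.

- **Hyperparameter handling**: every grid point is a separate model
  configuration evaluated on the outer CV; the best model per resampling
  method is the argmax of macro-averaged AUC (ties → higher mean
  sensitivity, then lexicographically smaller configuration label). There
  is no inner CV, so the selected AUC is optimistically biased — but
  identically for every resampling method, which is what the comparison
  needs.
- **Macro-averaging**: arithmetic mean over all folds of all repeats.
- **Resampler parameter variants** (e.g. SMOTE k = 3 vs 7) count as
  separate methods in rankings and agreement, mirroring how such results
  are reported per variant.
- **Seed scheme**: a master seed expands through `numpy.random.SeedSequence`
  into per-repeat fold seeds and per-fold stage seeds (resampler, selector,
  classifier), so no stream is reused and a full run is bit-reproducible.

## Agreement and similarity

Selected feature sets are compared pairwise between methods on every fold
and averaged. Jaccard (|A∩B|/|A∪B|) and Ochiai (|A∩B|/√(|A||B|)) measure
set agreement. Because correlated features carry overlapping information,
two further measures use the feature correlation matrix (absolute Pearson,
computed on the preprocessed table — similarity of information content is
sign-agnostic):

- **Max-correlation similarity**: for each feature of one set, the best
  |correlation| to any feature of the other set; the symmetrized mean of
  these maxima. Equals 1 iff the sets share all features up to perfect
  correlation; monotone in every |R| entry.
- **Zucknick measure**: Jaccard credited with cross-set correlations,
  `S = (|A∩B| + C(A,B) + C(B,A)) / |A∪B|` with
  `C(X,Y) = (1/|Y|) Σ_{x∈X\Y} Σ_{y∈Y} |R(x,y)|·1{|R(x,y)| ≥ τ}`, default
  threshold τ = 0.8, clipped to [0,1]. The exact published variant of this
  measure exists in several forms; this one is isolated behind a single
  function so it can be swapped without touching callers.

Degenerate conventions are explicit: Jaccard of two empty sets is defined
as 1 (with a warning); the other measures require nonempty sets.

The core qualitative phenomenon the package reproduces as a property: on
block-correlated data, sets selecting *different members of the same
blocks* have Jaccard 0 but max-correlation similarity ≈ ρ.

## Cross-dataset statistics

On the datasets × methods matrix of best-model AUCs: mean/max gains vs. the
no-resampling baseline; within-dataset ranks (1 = best, mid-rank ties);
pairwise win–loss counts with 0.5 per draw (so W(i,j) + W(j,i) = number of
datasets; the diagonal is n/2 by the same convention); the Friedman test
`χ²_F = [12n/(k(k+1))]·Σ_j (R̄_j − (k+1)/2)²` with the mid-rank tie
correction `C = 1 − Σ(t³−t)/(nk(k²−1))` and p from χ²(k−1); and the
Nemenyi post hoc, `q = |R̄_i − R̄_j| / √(k(k+1)/(12n))` referred to the
Studentized range distribution with k groups and infinite degrees of
freedom. The Friedman implementation matches `scipy.stats.friedmanchisquare`
to 1e−8 on tie-free data; the Nemenyi p-values are verified against the
Studentized range survival function on hand cases. Tie handling differs by
design between statistics (mid-ranks) and win–loss (0.5 points), matching
how each is conventionally reported. Significance level 0.05, two-sided.

## Problem sizes in tests and the acceptance script

The shipped suites use scaled-down study conditions chosen once: oracle
equivalence on 200 random instances with n ≤ 30, d ≤ 5; signal recovery at
n = 200, d = 200 with one informative block (δ = 2, ρ = 0.8) under
5-fold × 5-repeat CV and a 12-configuration grid; a null control (δ = 0)
on the same shape; and a three-dataset end-to-end study (n = 80, d = 60,
B = 2.2, δ = 1.5) with a reduced grid. These sizes give stable results —
the recovery error stays within ±0.05 of the analytic oracle across seeds —
while keeping a full run in seconds.

## Known limitations

- The generator's linear-Gaussian correlation structure is a simplification
  of real radiomic dependence; conclusions about real data require real
  data.
- Best-model selection on outer-CV AUC is optimistically biased (shared
  equally across methods, but absolute AUCs should not be read as unbiased
  estimates).
- The Zucknick variant implemented here follows the cited construction but
  published variants differ in normalization; the default threshold 0.8 is
  a convention.
- Binary classification only; multi-class imbalance is out of scope.
- No external test sets: repeated CV measures internal robustness, not
  generalization to new cohorts.
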