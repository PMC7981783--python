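# Methods

## The model

`braincca` analyses two subject-aligned data blocks: an imaging block X
(n subjects × p continuous morphometric features such as regional
cortical thickness, surface area or subcortical volume, plus global
measures) and a non-imaging block Y (n × q mixed demographic,
anthropometric, cognitive and behavioural variables, treated as numeric
after coding ordinal scales as integers and binary variables as 0/1).
Sparse canonical correlation analysis finds paired linear combinations
("canonical variates") X·wx and Y·wy that are maximally correlated,
with L1 constraints that drive most weights exactly to zero.

The solver is a penalized matrix decomposition with alternating
soft-threshold updates:

    maximize  wxᵀ (XᵀY) wy
    s.t.      ‖wx‖₂ ≤ 1, ‖wy‖₂ ≤ 1,
              ‖wx‖₁ ≤ cx·√p, ‖wy‖₁ ≤ cy·√q,   cx, cy ∈ (1/√dim, 1]

With wy fixed, the optimal wx is the L2-normalized soft-thresholding of
XᵀY·wy; the threshold Δ is zero when the L1 bound is slack and otherwise
chosen so the bound binds. Δ is computed in closed form: on the interval
of thresholds where the active set consists of the k largest entries,
the condition ‖S(a,Δ)‖₁ = c·‖S(a,Δ)‖₂ is a quadratic in Δ; a bisection
(tolerance 1e-8 on the bound) remains as a fallback for degenerate
configurations, and exact ties at the maximum entry — where the
soft-threshold family jumps discontinuously — are resolved by spreading
the L1 budget equally over the tied entries, which is the exact optimum
on that face. Initialization is the leading right singular vector of
XᵀY (deterministic); iteration stops when the largest absolute weight
change falls below 1e-6 or after 1000 iterations; the covariance
objective is checked to be non-decreasing every iteration (violations
beyond bisection round-off flag the fit as non-converged). The reported
canonical correlation r is the Pearson correlation of the two variates,
reported non-negative by jointly flipping both weight vectors, with the
residual (wx, wy) → (−wx, −wy) ambiguity pinned by making the
largest-magnitude weight positive (this keeps fits equivariant under
feature permutation). Later modes deflate the cross-covariance matrix
by its rank-one projection on the found pair (Hotelling deflation);
variates and correlations are always evaluated against the original
data.

Note that the covariance criterion is a surrogate for correlation: the
two coincide when within-block feature correlations vanish, and on
standardized data with n ≫ p + q the unpenalized first-mode r sits
slightly below (typically within a few hundredths of) the classical
generalized-eigenvalue CCA correlation, which maximizes correlation
directly. The test suite asserts both the ordering and the small size
of this gap.

Per mode the package reports: the sparse weights; the canonical
correlation r; canonical cross-loadings (Pearson correlation of each
original variable with the opposite block's variate — Spearman is used
nowhere except the scan-quality analysis); the proportion of covariance
accounted for, r², rounded to an integer percent in reports; and the
reported-variable set, |cross-loading| strictly greater than 0.1 (the
small-effect floor).

## Tuning and inference

Sparsity candidates form a 10-point ladder per block, linearly spaced
from 1/√dim to 1 inclusive. All 100 combinations are fitted and the
pair maximizing the in-sample first-mode r is selected; exact ties
resolve to the lexicographically smallest pair (the sparser model).
In-sample r is an optimistic criterion and systematically prefers
weakly sparse models: on planted-mode data the selected penalties
recover the true direction almost perfectly (cosine > 0.95) while
keeping a fringe of small nonzero weights, so the nonzero pattern is a
superset of the true support. The optimism is mitigated downstream by
the robustness battery rather than by the tuning rule itself.

Significance uses an exact permutation P: the rows of Y are permuted
uniformly at random 1000 times (permuting either block is equivalent in
distribution), the first mode is refitted with the tuned penalties held
fixed — re-tuning inside each permutation would multiply the cost by
100 and is not what a once-tuned analysis does — and P is the fraction
of permutations with r at least the observed value. P may be exactly 0;
a conservative (count+1)/(n+1) variant is available. P values from the
model family are then Benjamini–Hochberg adjusted, and a mode counts as
significant only below an FDR-adjusted 0.001.

## Robustness battery

Four resampling analyses, all on 50% subsamples drawn without
replacement unless stated:

* **RR (redundancy-reliability) scores**, 500 resamples: per resample the
  model is refitted at fixed penalties and each full-sample reported
  variable (|cross-loading| > 0.1) is checked for replication — same
  sign and magnitude above 0.1 in the resample. The score is the
  replicated fraction; the published formula behind the name is not
  available, so this sign-and-threshold concordance, bounded in [0, 1]
  and compatible with the median > 0.80 criterion, is used and labelled
  as the package's definition. Resampled fits are sign-aligned to the
  full-sample fit through the weight inner products, so representation
  flips are not scored as failures while genuine loading reversals are.
* **Stability curve**: 100 refits at each fraction 10%–150% of n in 10%
  steps (1500 refits); fractions above 100% sample with replacement,
  which is the only way to exceed n.
* **Split-half generalization**, 500 splits: fit on a random half, apply
  the training weights to the held-out half, and compare mean test r to
  mean train r; the criterion is a test/train ratio of at least 0.80.
* **Quality association**, 500 resamples: Spearman correlation between a
  resample's mean scan-quality score and its refitted r; "coefficients"
  is read as the canonical correlation per resample.

A mode is flagged `reported` only if all three gates hold: FDR-adjusted
P < 0.001, median RR > 0.80, and test/train ≥ 0.80.

## Preprocessing

Stages run in a fixed order — impute → outlier filter → harmonize →
(change scores) → standardize — each establishing the next stage's
preconditions.

* **Imputation** (non-imaging block only): iterative random-forest
  regression in the missForest style — initialize missing cells at
  column means, then revisit columns from most to least complete,
  fitting a forest of each column on all others over originally
  observed rows and predicting the missing rows, until the relative
  change of imputed values falls below 1e-3, stops decreasing, or 10
  sweeps. Missingness is assumed completely at random. Deterministic
  given the seed.
* **Outlier exclusion** (imaging block, each sample separately):
  squared Mahalanobis distance from the column means under the
  classical sample covariance, with exclusion above the chi-square
  quantile (df = p) at 0.999; Ledoit-Wolf shrinkage is available when p
  approaches n, and a minimum-covariance-determinant robust variant is
  a flag. Distances are computed on imaging features only by default.
* **Harmonization** (imaging block only): parametric empirical-Bayes
  location-scale adjustment (ComBat). Features are standardized with a
  batch-design fit, per-site shift and scale estimates are shrunk
  toward pooled priors by the iterative posterior-mean solution, and
  the adjusted data are back-transformed. Biological covariates can
  optionally be protected via the `preserve` argument; the default
  protects none. The implementation is cross-checked against
  `sva::ComBat` (R) to 1e-4 in the test suite. Because shrinkage pulls
  per-feature site effects toward the pooled prior, observed site-mean
  gaps after adjustment are at sampling-noise scale rather than exactly
  zero.
* **Change scores**: per variable, follow-up minus baseline,
  residualized on the baseline value by simple OLS with intercept;
  residuals are exactly uncorrelated with baseline, removing
  regression-to-the-mean coupling.
* **Standardization**: z-scores with the n−1 denominator; zero-variance
  columns are an error, not a silent drop.
* **Covariate removal** (sensitivity analyses): OLS residualization of
  every column of both blocks on the covariates (e.g. age and sex),
  after which the pipeline is re-run to check that a mode is not purely
  covariate-driven.

## Synthetic cohorts

The generator emulates a multi-site adolescent neuroimaging cohort as an
inter-battery factor model: per mode, a standard-normal latent score per
subject projects onto sparse unit weight vectors in both blocks, plus
independent Gaussian feature noise. The signal amplitude a solves
r = a²/(a² + σ²), so the population correlation of the true variates is
the spec's `target_r` exactly. True weights have equal-magnitude
entries ±1/√support with random signs — the standard sparse-recovery
simulation design; heterogeneous weight magnitudes leave L1 slack that
makes the thresholded estimate keep a fringe of noise features, which is
worth knowing when interpreting support-recovery results. Mode supports
are drawn disjointly when the feature budget allows, making planted
modes orthogonal.

Site effects are additive (per-site, per-feature shifts ~ N(0, 0.4)) and
multiplicative (scales ~ U(0.8, 1.25)) on the imaging block only, sized
to produce clearly visible (> 0.2 SD) batch structure since no
empirical effect sizes are available to copy. Missingness is injected
completely at random into the non-imaging block only. Longitudinal
pairs add, at follow-up, a per-subject thinning decrement
~ N(−0.12, 0.06) — matching the reported mean (SD) decrease of global
cortical thickness in mm over the inter-scan interval — applied to all
imaging columns (all are treated as thickness-like), plus a fresh draw
of the linked-mode signal so change scores carry their own canonical
structure with the same true weights. Ordinal/binary non-imaging
variables can be produced by thresholding latent Gaussians into category
codes; the default cohort keeps Y continuous so noiseless limits are
exact.

What the generator does not emulate: missing-not-at-random mechanisms,
site-by-covariate confounding, non-Gaussian morphometric distributions,
heteroscedastic measurement error across regions, and realistic
within-block correlation structure beyond what the shared modes induce.
Passing tests therefore demonstrate correctness of the machinery under
a known factor model, not performance guarantees on real cohort data.

## Problem sizes and numerical choices

Test-suite simulations run at desk scale chosen as the smallest sizes at
which the statistical behaviour under test is stable: recovery studies
at n = 1000 with p = 50/q = 40; type-I error at 500 replicate null
datasets of n = 100, p = q = 20 with 99 permutations; the
robustness-gate study at n = 500, p = 30, q = 20 with 1000 permutations
and 200 resamples/splits per seed (medians and means of the resampling
summaries are stable well below the 500 defaults, which remain the
pipeline's runtime defaults). Seeds are fixed everywhere; identical
configurations reproduce byte-identical reports.

Degenerate inputs are handled explicitly: constant features error in
standardization and pass through harmonization with a warning; a
singular covariance in the outlier filter suggests the shrinkage
option; zero-variance variates invalidate cross-loadings; subsets
smaller than 3 rows are skipped in the stability curve with a warning;
resamples with degenerate test variates are recorded as missing in the
split-half table.

## Known limitations

* The covariance-vs-correlation surrogate gap means unpenalized fits
  are not exactly classical CCA at finite n (see above); analyses that
  need exact CCA should use a dedicated generalized-eigenvalue routine.
* In-sample-r tuning does not consistently recover the exact sparsity
  level of a planted mode (direction yes, support only approximately);
  support-selection consistency would require a held-out or
  permutation-based tuning criterion, which is out of scope.
* The RR score is this package's concordance definition, not a
  published formula.
* Modes beyond the first depend on the deflation choice and should be
  interpreted cautiously; only first modes pass the robustness gates in
  typical runs.
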