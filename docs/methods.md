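# Methods

## The model

The workflow assumes that the metabolome of a study population is organized
by a small number of latent metabolic factors.  On the measurement side,
each platform's log-intensities decompose as

    x_j = mu_j + lambda_j' z + e_j

with z the latent factor vector, lambda_j the variable's loadings and e_j
unique noise.  After standardization, the combined maximum-likelihood
factor model is Sigma = Lambda Lambda' + Psi on the pooled correlation
matrix, fitted by minimizing the ML discrepancy
`ln|Sigma| + tr(S Sigma^-1) - ln|S| - p` and varimax-rotated.  On the
population side, samples fall into a small number of metabotypes that
differ in their factor means; clustering the per-sample factor scores
recovers them.

The central methodological commitments are:

- **Variable retention by saturation.**  After each rotated fit (PCA and
  ML-FA), a variable is kept only when its top absolute loading is > 0.5
  and exceeds the second-largest by >= 0.1.  Cross-loading ("doubly
  saturated") features and features without a clean factor home are
  discarded; this is the mechanism that reduces hundreds of redundant
  untargeted features to an interpretable factor structure.
- **Sequential reduction.**  Decorrelation (intra- then inter-matrix
  Pearson screen at |r| >= 0.9, dropping the member of each offending pair
  with the larger mean absolute correlation), then per-matrix PCA -> ML-FA,
  then one combined ML-FA over the pooled survivors.  Per-matrix component
  counts use the Kaiser-Guttman rule (eigenvalues of the correlation
  matrix > 1, floor 1) raised until cumulative explained variance exceeds
  60%; the scree elbow is reported as a diagnostic only.
- **Validation by discriminant analysis.**  Ward clustering (squared
  Euclidean, heights = within-cluster sum-of-squares increments) of the
  regression factor scores proposes partitions at k = 2, 3, 4; linear DA
  with leave-one-out cross-validation scores each; the argmax k is chosen.
  Ties go to the **largest** k: with perfectly separated clusters every
  coarsening is also perfectly separable, so the most granular partition
  the DA maximally supports is the informative one.

## Numerical choices

- **ML-FA** is fitted by profiling the likelihood over the loadings: for
  fixed uniquenesses Psi the optimal Lambda is closed-form in the
  eigensystem of `Psi^-1/2 S Psi^-1/2`, and the concentrated discrepancy
  `sum_{j>k} (lambda_j - ln lambda_j - 1)` is minimized over Psi by
  L-BFGS-B with analytic gradients, bounds [0.005, 1] (Heywood protection)
  and a deterministic principal-axis start (tolerance 1e-6, <= 1000
  iterations; non-convergence raises).  A plain EM iteration converges far
  too slowly for over-factored fits.  The factor count is additionally
  capped by the Ledermann bound (identifiability).  Reported uniquenesses
  are `clip(1 - communality, 0.005, 1)` so communality + uniqueness = 1
  holds exactly.
- **Varimax** uses classical Kaiser pairwise (Jacobi) planar rotations with
  row normalization — monotone in the criterion, whereas the SVD-based
  update can oscillate on balanced block structures.  Sign convention:
  each column's largest-magnitude loading is positive; columns are ordered
  by explained sum of squares.
- **Minimum two indicators per factor.**  After retention, a factor
  saturated by fewer than two variables is invalidated and its variables
  released (reason `singleton_factor`).  A single-indicator "factor" is an
  unidentified artifact — typically a Heywood case of an over-factored ML
  fit — and without this rule a pure-noise matrix would retain ~35% of its
  variables through spurious singleton factors instead of <= 10%.
- **KMO** follows the partial-correlation definition
  `sum r_ij^2 / (sum r_ij^2 + sum p_ij^2)`; a singular correlation matrix
  gets a 1e-8 ridge (logged).
- **QC-SVRC defaults** are scale-aware per feature: C = QC intensity range,
  gamma = 1/(injection-order range)^2, and epsilon = 2 x 1.4826 x MAD of
  the QC trace after removing a low-order polynomial trend — the tube must
  reflect measurement noise, not the drift being corrected.  The correction
  divides by the fitted trend scaled to its own median over the QC orders,
  so a flat trend is an exact identity and rerunning the pipeline on its
  own output changes values by well under 1%.  Correction is multiplicative
  because intensities are positive and drift is gain-like.
- **Pipeline order** is impute -> SVRC -> CV filter -> IS normalization ->
  (log10 +) outlier screen; filtering after correction lets features whose
  QC variation was pure drift survive.  Outlier screening flags samples
  whose Hotelling T2 on the first two PCA scores exceeds
  `(2(n-1)/(n-2)) F(1-alpha; 2, n-2)`; removal is a separate, explicit
  decision.

## The synthetic generator

`default_ground_truth()` encodes the study conditions the pipeline is
validated against: five platforms with (345, 170, 63, 242, 91) features,
six latent factors, and three metabotypes of sizes (74, 10, 16) whose
factor means follow the three-cluster pattern in
`DEFAULT_CLUSTER_FACTOR_MEANS`.

- **Factor blocks.**  Each factor loads one block of one platform's
  features (three lipid-class blocks of 20/13/10 features on LC-MS(+), an
  11-feature free-fatty-acid block on LC-MS(−), a 12-feature amino-acid
  block on GC-MS, a 5-feature block on CE-MS(+); CE-MS(−) carries none).
  Block features are factor signal plus unique noise whose sd is set per
  factor so the standardized within-block loading is 0.90 at the default
  noise level — within-block r ~ 0.81, i.e. strongly coherent classes that
  still survive the 0.9 decorrelation screen.
- **Diffuse features.**  Features outside the blocks are not white noise.
  They come in large redundancy families (~35 members, within-family
  r ~ 0.97 — adducts, isotopologues, in-source fragments and co-regulated
  species of one compound class) that the intra-matrix decorrelation stage
  collapses to one representative, and each family cross-loads on two
  latent factors (the platform's own factors first, padded with the factor
  least correlated with the anchor) at standardized loading 0.6 each with
  random signs — genuine double saturation that the retention rule
  discards.  This mirrors real untargeted data, where the cascade's
  attrition comes from redundancy and cross-loading rather than from
  independent noise: an earlier all-i.i.d.-noise design made the
  Kaiser-Guttman rule over-factor badly at p ~ n (sample correlation
  eigenvalues of independent features exceed 1 mechanically), let
  spurious singleton factors retain noise, and pushed the pooled variable
  count past the sample count, where the pooled correlation matrix is
  singular and ML-FA is undefined.
- **Latent geometry.**  Factor scores of an orthogonally rotated model are
  close to uncorrelated over the whole study, so the within-cluster
  covariance partially cancels the between-cluster covariance implied by
  the metabotype means (`W = diag(s^2 (1 - b_ff)) - gamma offdiag(B)` with
  the largest gamma in [0, 1] keeping W positive definite).  The
  within-cluster spread is s = 0.45 of the standardized residual sd.  A
  unit-variance Gaussian mixture with these means is far more overlapped
  than the clusters the published workflow recovered (Ward then reaches
  adjusted Rand ~ 0.4 against truth and the DA validation collapses to
  k = 2); s is calibrated so the pipeline reproduces the reported outcome —
  clean recovery of three metabotypes of sizes (74, 10, 16) with
  cross-validated DA accuracy in the mid-90s-to-100% range.
- **Acquisition artefacts.**  Pooled QCs are the study-mean profile times
  ~2% multiplicative noise (1 QC per 10 study samples, minimum 5, spread
  along the sequence with blanks at both ends); drift multiplies study and
  QC samples alike by `1 + a sin(pi o/O) + b o/O` of injection order o
  (defaults a = 0.3, b = 0.2) — smooth, with monotone and curved
  components, the regime an RBF SVR can fit; missingness is completely at
  random at rate 0.02; one internal-standard channel per platform is a
  constant times 2% noise, never missing and never drifting.

What the generator does **not** emulate: intensity-dependent (censored)
missingness, multi-batch structure, chromatographic or m/z-level artefacts,
non-Gaussian within-cluster shapes, and annotation (factor interpretation
is by planted membership, not chemistry).  Passing the recovery tests
therefore shows that the cascade's selection, retention, pooling, scoring
and validation logic is correct under realistic dimensionality, redundancy,
drift and missingness — not that the workflow is robust to every artefact
of real acquisitions.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `knn.k` | 5 | neighbours for imputation (standardized Euclidean over co-observed features) |
| `cv_filter.max_cv_pct` | 30 | QC CV threshold, percent |
| `svrc.C / epsilon / gamma` | auto | scale-aware per feature (see above) |
| `outliers.alpha` | 0.05 | Hotelling T2 ellipse level (2 components, log10) |
| `decorrelation_threshold` | 0.9 | Pearson multicollinearity screen |
| `retention_threshold / gap` | 0.5 / 0.1 | saturation and double-saturation rules |
| `min_cum_var` | 0.60 | cumulative-variance rule for component counts |
| `candidate_k` | (2, 3, 4) | metabotype counts scored by LOO linear DA |

All are exposed on `PipelineConfig` and the CLI.

## Known limitations

- The Kaiser-Guttman rule over-selects components whenever many mutually
  independent features are present at p ~ n; the cascade relies on the
  retention and minimum-indicator rules to undo this, which is faithful to
  the workflow but means per-matrix component counts should be read as
  upper bounds.
- Orthogonal (varimax) rotation of factors that are truly oblique — e.g.
  correlated through strong cluster structure — attenuates the match
  between regression scores and the underlying factors; with the default
  geometry all matched score-factor correlations stay >= ~0.8, but more
  oblique structures would need an oblique rotation, which is out of scope.
- Leave-one-out DA validates a partition's linear separability, not its
  existence; with strongly nested structure several k can reach identical
  accuracy, which is why ties resolve to the largest candidate.
- ML-FA requires the pooled correlation matrix to be nonsingular, i.e.
  fewer pooled variables than samples; studies whose cascade retains more
  must tighten the upstream thresholds.
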