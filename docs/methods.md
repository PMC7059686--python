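# Methods

This note records the statistical model, the preprocessing contracts,
the simulator's generative assumptions and the numerical choices made
where the design was genuinely open.

## The variability model

Each feature (protein or peptide) is analyzed independently with a
fixed-effects general linear model containing main effects only:
continuous covariates enter first (in user order), then the categorical
workflow factors (in user order), each coded as treatment dummies
against its first-appearance level.  The total sum of squares about the
feature's mean is decomposed **sequentially** (Type-I): every term's SS
is the reduction in residual SS when that term joins the nested model.
Numerically this is read off a single QR factorization of the design
matrix — the squared projections of the response onto the Q columns of
each term's block — which is algebraically identical to the nested
least-squares definition (the test suite checks this against an
explicit nested-projection oracle at 1e-8 on random small designs, and
against statsmodels' Type-I ANOVA).

Why sequential SS: with covariates first, factors are adjusted for the
covariates (the ANCOVA convention), and on balanced complete designs —
the intended use, a planned workflow-comparison experiment — the factor
blocks are mutually orthogonal, so factor SS is order-invariant and
equals partial SS.  On unbalanced data (after feature exclusion the
design stays balanced per feature only if whole features are dropped,
which is the case here) the user-given order is the declared meaning.

No interactions are fitted: the tool reports "SS due to each variable",
one row per variable; a workflow-standardization screen asks which
*step* is most variable, not which combination.

Per term: %SS = 100·SS_term/SS_total with the residual reported as its
own share, so the shares of all terms plus the residual sum to 100.
F = (SS_term/df_term)/(SS_res/df_res); p from the F upper tail.
Constant features (zero total SS at relative tolerance 1e-10) get all
SS and %SS set to 0 and missing p-values; they are kept in the tables
but skipped by the significance counts and the %SS summary.

P-values are adjusted **across features, separately per term** (the
multiplicity being controlled is over features).  All six classic
procedures are implemented natively: Bonferroni, Holm (step-down),
Hochberg and BH/BY (step-up with cumulative minima), and Hommel via the
standard O(n²) step-wise algorithm.  Two independent cross-checks run
in the tests: literal textbook definitions (Hommel by explicit closed
testing over all subset Simes tests) and statsmodels.

## Coefficient of variation

For every level of every selected categorical variable,
CV = 100·(sample SD, n−1)/(sample mean) per feature over the samples at
that level.  CV is computed on the **same preprocessed matrix that
enters the model stage**, so the SS and CV rankings refer to the same
scale and are comparable with each other.  Caveat: on log-like scales
(log2/glog) this is the CV *of the transformed intensities*, not the CV
of raw intensities; because the transform is shared by all groups, the
*ordering* of groups — the quantity used to pick the better option — is
what the tool interprets, not the absolute percentage.  Cells with
fewer than two observed values or with mean ≤ 1e-12 are reported
missing rather than infinite.

## Normalization

* **log2** — elementwise; non-positive raw values cannot be transformed
  and become missing, with a warning counting them (no silent
  pseudo-count, which would invisibly shift downstream SS).
* **Quantile normalization** — applied to the log2 data.  The reference
  distribution is the across-sample mean of order statistics, built
  from observed values only (incomplete columns contribute through
  linear quantile interpolation onto a common grid).  Each column's
  observed values map to the reference by rank; ties receive the
  average of the reference values at their tied ranks (deterministic).
  Missingness is preserved exactly.
* **VSN** — fitted on the raw scale.  The transform for sample *s* is
  h_s(x) = arsinh(a_s + b_s·x)/ln 2 with b_s > 0, which behaves like
  log2(x) + log2(2·b_s) at high intensity and is linear near zero.
  (a_s, b_s) are estimated by profile maximum likelihood under the
  model h_s(x_is) = μ_i + ε, ε ~ N(0, σ²), with row means and σ²
  profiled out and the log-Jacobian term retained (it prevents the
  transform from collapsing).  Optimization: L-BFGS-B on
  (a_s, log b_s) with an analytic gradient, deterministic column
  median/MAD initialization, ftol 1e-15 / gtol 1e-10, up to 2000
  iterations.  A floor of 1e-18 on the per-entry mean squared residual
  keeps the objective finite when samples are exactly collinear (pure
  dilution series), in which case the fit drives the transformed
  columns equal to ~1e-8.  Fitting requires ≥ 10 complete features;
  below that the error message suggests log2 + QN.
* **none** — pass-through for data the user normalized elsewhere.

QN and VSN can run group-wise on the `Norm_Imp_Group` partition; each
group is normalized fully independently (no shared reference
distribution), matching the semantics of applying the method per group.

## Imputation

Both methods assume MAR/MCAR; left-censored (MNAR-aware) imputation is
deliberately out of scope.  Observed cells are never modified and no
missing cell remains afterwards.

* **KNN** (k = 10 by default): donors are other features; distance is
  the root-mean-square difference over coordinates observed in both
  rows (rescaling by the shared-coordinate count keeps rows with
  different overlaps comparable, and avoids requiring complete donors).
  Missing cells are 1/distance-weighted averages of donor values,
  skipping donors missing there; exact duplicates (distance 0) are
  averaged unweighted.  Ties in distance break by feature input order
  for bit-reproducibility.  Features missing more than half their
  samples (configurable) fall back to per-sample column means.
* **Iterative SVD** (rank 2 by default): initialize missing cells with
  row means, then alternate rank-r truncated SVD reconstruction of the
  filled matrix with re-filling of the missing cells, until the
  relative change of imputed values < 1e-6 or 100 iterations.  This is
  alternating minimization of ‖X_fill − rank-r approx‖_F, which is
  non-increasing by construction (each half-step minimizes it); the
  step size between successive fills is *not* monotone and is only used
  as the convergence measure.

Defaults (k = 10, rank = 2, 0.5 row-missingness fallback) follow the
conventional defaults of these method families and are CLI-overridable.

## Pipeline order

* Exclude mode: drop features with any missing value → normalize →
  aggregate.  Dropping first keeps the QN reference distribution free
  of NA handling in the simple path.
* Impute mode: normalize → impute **at the level the data was
  provided** → aggregate.  Peptide data analyzed at protein level is
  imputed at peptide level first, then rolled up.

Aggregation (mean/median/sum/maximum per protein, missing values
skipped unless all contributors are missing; `sum` of an all-missing
group is missing, not 0) runs on the matrix in its current scale, so
both modes reach the model stage on the same scale.  Every stage logs
feature/sample/missing counts for auditability.

## The simulator

`SimulationDesign` defaults emulate a two-step workflow comparison:
200 proteins quantified via 1000 peptides (every protein gets at least
one peptide; the rest are assigned uniformly at random), factors
M1 ∈ {A1, A2} (storage) and M2 ∈ {B1, B2, B3} (extraction), 3
biological replicates per cell, 2 MS runs → 36 samples, and subject age
(uniform 25–65, shared by a subject's two runs) as covariate.

Log2-scale signal:  baseline(protein) ~ N(20, 1.5²), peptide offset
~ N(0, 0.4²), plus per-protein responses e ~ N(δ_level, τ²) for each
factor level and a per-protein age slope ~ N(0.01, 0.005²).  Defaults:
δ_M1 = {0, 0.3}, δ_M2 = {0, +0.6, −0.6}, δ_run = {0, 0.15};
τ_M1 = 0.3, τ_M2 = 0.5, τ_run = 0.25.  Residual noise per sample has
SD √(σ_M1² + σ_M2²) with σ(A1) = 0.45 > σ(A2) = 0.30 and
σ(B2) = 0.30 < σ(B1) = 0.45 ≤ σ(B3) = 0.50.  Missingness is MCAR at 5%
by default, with an optional logistic intensity-dependent (MNAR)
mechanism for robustness studies.  Data is exported on the raw scale
(2^value); the ground-truth record keeps every drawn parameter and the
complete pre-masking matrix.

Two modelling points behind these choices:

* **Effects must be protein-specific.**  A level effect identical for
  every feature is a per-sample calibration shift, and QN/VSN absorb
  such shifts by construction — with feature-constant effects the
  normalized data carries almost no factor signal.  Real proteins
  respond differently to storage/extraction; the τ spreads encode that,
  and it is this heterogeneity that the SS decomposition measures after
  normalization.  The τ ordering (τ_M2 > τ_M1, age spread smallest)
  makes extraction the dominant variability source, storage second and
  age least — chosen from the expected-SS calculation
  E[SS_factor] ≈ n_level·[Σ(δ_l−δ̄)² + (k−1)τ²].
* **Noise SD orderings drive the CV conclusions** (A2 < A1 within
  storage; B2 smallest within extraction), with ratios ≥ 1.5 so the
  median-CV ranking is recoverable.

What the simulator does **not** emulate: correlated peptide noise
within a protein, intensity-dependent (heteroscedastic-in-mean) noise,
shared-peptide/razor-protein ambiguity, batch drift within a run, or
real MNAR censoring by default.  Passing tests therefore demonstrate
correctness of the computation and recoverability under the stated
generative model, not performance on any particular real dataset.

## Test and script problem sizes

The ranking-replication checks run the full demonstration scale
(1000 × 36, 20 seeds) — small enough to complete in well under a minute
— because near-tied minor terms (M1/Run/Age) swap ranks at much smaller
feature counts purely through median noise.  Oracle-equivalence checks
use 100 random designs with n ≤ 12 and the Hommel closed-testing oracle
is limited to vectors of length ≤ 10 (subset enumeration is 2^n).  The
type-I calibration uses 1000 null features, where the binomial band
0.05 ± 0.02 is ≈ ±3σ.

## Known limitations

* Unbalanced designs make factor SS order-dependent (inherent to
  Type-I); the term order is the user's declaration of priority.
* CV on log-scale data is not the CV of raw intensities (see above).
* VSN is a contract-level reimplementation (affine-calibrated glog,
  variance-stabilization likelihood, log2 asymptote); it is not
  bit-compatible with any particular reference implementation.
* The KNN imputer is O(n_incomplete · n_features) per call; for
  matrices far beyond ~10⁴ features the SVD imputer is the practical
  choice.
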