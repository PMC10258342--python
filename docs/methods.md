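# Methods

## Model

One trait at a time, the package assumes the standard germplasm-trial
random-effects structure. Within a year,

    y_ik = μ + g_i + ε_ik,          g_i ~ N(0, σ²g),  ε_ik ~ N(0, σ²ε)

and across years,

    y_ijk = μ + Y_j + g_i + (gY)_ij + ε_ijk,
    g_i ~ N(0, σ²g),  (gY)_ij ~ N(0, σ²gy),  ε_ijk ~ N(0, σ²ε),

with all random terms mutually independent and homoscedastic. Year is a
**fixed** effect: the target quantity, across-year repeatability
`R2 = σ²g / (σ²g + σ²gy/nl + σ²ε/(nl·nr))`, contains no year-variance
term, so the year stratum must not contribute random variance. Accession
replicates label scan batches within a cell; they are exchangeable and
never matched across accessions.

## Variance-component estimation

**Balanced path.** For balanced data the ANOVA strata are independent
scaled chi-squares and the method-of-moments (expected-mean-squares)
estimators are also the REML estimators whenever they are interior:

    σ̂²ε  = MS_e
    σ̂²gy = (MS_gy − MS_e) / nr
    σ̂²g  = (MS_g − MS_gy) / (nl·nr)      (single-year: (MS_g − MS_e)/nr)

Negative solutions are clamped at zero and flagged (`truncated`), without
re-solving the reduced model — the flag preserves the information that the
data sat on the boundary. Standard errors use the large-sample mean-square
variance `Var(MS) = 2·MS²/df` propagated through the linear combination;
this is the classical balanced-ANOVA approximation and is reported as
such.

**Restricted likelihood on balanced data.** The error contrasts factor
into strata with `SS_k/λ_k ~ χ²(df_k)` where the stratum variances
`λ_e = σ²ε ≤ λ_gy = σ²ε + nr·σ²gy ≤ λ_g = λ_gy + nl·nr·σ²g` are ordered
by the non-negativity constraints. The constrained REML maximum is the
isotonic regression of the stratum mean squares (pool adjacent
violators); the package uses this exact closed form for the balanced
restricted log-likelihood and the likelihood-ratio test, avoiding any
iteration.

**General path (EM-REML).** `em_reml` implements the standard EM
iteration on `V = Σ σ²_r Z_r Z_rᵀ + σ²ε I` with
`P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹`:

    σ²_r ← σ²_r + (σ²_r²/q_r)·(yᵀP Z_r Z_rᵀ P y − tr(Z_rᵀ P Z_r))

and the analogous residual update. The iteration keeps every component
non-negative and the restricted log-likelihood monotonically
non-decreasing (asserted at run time). Defaults: tolerance 1e-8 on the
maximum component change, 10 000 iterations, initialisation at a
moment-style split (mean within-cell variance for σ²ε, the remainder
divided evenly) floored at 1e-6 × the total variance. Standard errors on
this path come from the inverse expected information
`I_rs = ½·tr(P A_r P A_s)` at convergence. Dense linear algebra is used
throughout; the intended problem sizes (tens of accessions, a few
hundred observations) make this exact and fast.

**Genotypic significance.** The LRT compares the full model against
`σ²g = 0` under the same fixed-effect structure (a requirement for REML
comparisons). Because the null lies on the parameter boundary, the
reference is the mixture ½χ²₀ + ½χ²₁: `p = ½·P(χ²₁ ≥ LR)` for `LR > 0`
and `p = 1` at `LR = 0`. Empirical size at the 15 × 3 design is checked
by simulation in the acceptance suite (2000 null replicates).

**LSD.** `lsd = t(1−α/2, df_e) · sqrt(2σ̂²ε/n_eff)` with `n_eff` the
replication of an accession mean: `nr` within a year, `nl·nr` across
years.

## Repeatability and BLUP

`R1` and `R2` are computed exactly as stated above from whatever
components are supplied; clamped (zero) components feed the ratio as
zero, with no back-substitution, so the reported repeatability always
corresponds to the reported components. Both are intraclass
correlations and live in [0, 1].

For the balanced random-intercept structure the BLUP of an accession
effect has the closed form `ĝ_i = λ·(ȳ_i − ȳ)` with `λ` equal to the
matching repeatability — this identity is asserted in tests rather than
assumed. The across-years matrix therefore *is* the mean matrix adjusted
for genotype-by-year interaction: σ²gy enters the shrinkage denominator
and pulls accession predictions toward the grand mean. General
mixed-model equations are deliberately not solved; the balanced closed
form is exact, transparent and testable.

A caution for comparisons with published tables: repeatabilities
recomputed from *rounded, printed* variance components generally do not
reproduce published repeatability values (rounding, a different
effective replication, or unclamped components may intervene). This
package always reports the exact ratio of its own full-precision
estimates.

**Degenerate traits.** When σ̂²g clamps to zero the shrinkage is total
and the trait's BLUP column is constant. Correlations and
standardization are undefined for a constant column and raise a clear
error naming the trait; `BlupMatrix.drop_constant()` removes such
traits, and the analysis drivers use it (reporting what was dropped).
Under the default generator's components one trait (hilum W/L, with
σ²g = 0.016 against σ²ε = 0.382) hits this boundary in a substantial
fraction of 15-accession realisations — that is a property of the study
conditions, not an artifact.

## Correlations

Phenotypic correlations are Pearson correlations of the accession BLUP
means (n = number of accessions), with two-sided p-values from
`t = r·sqrt((n−2)/(1−r²))` on `n−2` df and stars at 0.05/0.01. No
multiple-testing correction is applied — the tables follow the
conventional per-pair star notation. A components-based phenotypic
covariance was considered and not implemented as the default: the
BLUP-mean route is reproducible from the released matrices alone.
MANOVA sums of cross-products are reported as a between-accession and a
residual stratum after removing year means; between + within equals the
year-adjusted total on balanced data, and the univariate diagonals match
the ANOVA mean squares. Trait-environment correlations reuse the same
machinery over a joint traits + covariates matrix.

## Pattern analysis

The BLUP matrix is standardized trait-wise (mean 0, sample sd 1 with the
n−1 denominator) because the traits mix units (mm, g, ratios). PCA is
the eigendecomposition of the correlation matrix of the standardized
values; scores are `z·V`, loadings `V·sqrt(eigval)`, and the percentage
of variation is the normalised eigenvalue. Sign convention: within each
component the loading of largest magnitude is made positive, ties broken
by the earliest trait index — biplots are then reproducible across
platforms and BLAS builds.

Clustering is agglomerative with Euclidean distance and Ward linkage
(the default of the germplasm pattern-analysis tradition; overridable
via `linkage=`), cut at a user-chosen k — truncation levels are an
analyst's decision, not automated. Group ids are assigned 1..k in order
of first accession appearance. Merge heights are non-decreasing for
Ward; exact-tie merge order follows the distance implementation and is
deterministic for fixed input order. Group trait means are reported in
original units with group sizes.

## Synthetic data

The generator mirrors exactly the structure the estimators assume:
`y_ijkt = μ_t + Y_jt + g_it + (gY)_ijt + ε_ijkt`, all draws normal,
genotype effects multivariate normal across traits with covariance
`diag(s_g)·ρ·diag(s_g)`, interaction and residual draws
trait-independent. One integer seed drives three per-stratum substreams
via `SeedSequence.spawn`, so a dataset is bit-reproducible and partial
re-runs stay aligned.

The default configuration is a 15-accession × 2-year × 3-replicate trial
of nine seed traits whose means, per-year offsets, variance components
and cross-trait genetic correlation pattern (projected to the nearest
positive semi-definite correlation matrix) are those of a high-altitude
legume germplasm reference trial. Year effects are the per-year trait
means re-centred to sum to zero; repeatability is invariant to them, and
a dedicated fixture exercises non-zero offsets.

What the generator does **not** emulate: seed-level measurement (values
are replicate means of 100-seed scans — the model the estimators assume),
scan-batch vs biological replicate variance (conflated, as in the
analysis model), spatial or maternal-environment structure, non-Gaussian
noise, and by-design unbalance beyond random record deletion
(`drop_records`). Passing tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to violations of
them.

## Problem sizes and tolerances

The simulation experiments use: 100 random balanced one-way designs
(5–30 accessions, 2–5 replicates) for the EM-vs-closed-form sweep
(agreement < 1e-6 per component, interior solutions); 300 replicates of
the 15 × 2 × 3 design at (σ²g, σ²gy, σ²ε) = (0.2, 0.05, 0.1) for
parameter recovery; 2000 null replicates for LRT size; 400 replicates at
50 accessions for the across-years consistency check. These sizes give
Monte-Carlo standard errors comfortably below the asserted tolerances
while keeping the default suite quick. Equality-style numeric
assertions use 1e-8…1e-12 depending on how much float cancellation the
quantity admits; CSV round-trips are bit-exact (values written with
`repr`, parsed with correctly-rounded `float`).

## Known limitations

- Balanced-path estimators refuse unbalanced slices rather than
  silently reweighting; the EM path handles them but reports
  mean-square fields as NaN where strata are undefined.
- SEs of clamped components retain the unclamped large-sample formula;
  near the boundary they overstate uncertainty symmetry.
- The LRT's boundary mixture is asymptotic; at very small accession
  numbers (< 10) its size drifts below nominal.
- No narrow-sense heritability, kinship, multi-trait BLUP, spatial
  terms, or automatic group-count selection.
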