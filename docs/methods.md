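# Methods

This note records the models, conventions and design choices behind
`mpmrisk`, in the order the pipeline applies them.

## Stage-structured matrix models

A population is described by an annual projection matrix `A = U + F + C`
over `s` developmentally ordered stages: `U` carries survival-and-growth
transition probabilities (column sums at most 1), `F` per-capita sexual
recruitment, and `C` per-capita clonal recruitment. Validation enforces
finiteness, nonnegativity, shared dimensions and sub-stochastic `U`
columns (tolerance 1e-6). The dominant eigenvalue `λ` of `A` is the
asymptotic growth rate; its right and left eigenvectors give the stable
stage distribution `w` (normalized to sum 1) and reproductive values `v`
(normalized so `v·w = 1`). For imprimitive matrices (e.g. strict
biennials) several eigenvalues share the spectral radius; the Perron
root is identified as the one with the largest real part on the
spectral circle. Eigen-analysis is a deterministic dense decomposition;
no iterative solver is involved.

## The fourteen metrics

Nine life-history metrics are derived per matrix, five more from the
two-stage collapse below. Where the literature admits variants, the
convention used here is stated explicitly; these conventions are this
package's and are applied uniformly to every matrix.

* **Net reproductive rate** `R0`: dominant eigenvalue of `F·N` with
  `N = (I - U)^-1` the fundamental matrix. Column sums of `N` count the
  current year, so expected remaining lifetimes are ≥ 1 for survivors —
  an off-by-one convention that differs across references and is fixed
  here once.
* **Generation time** `T = log R0 / log λ`, reported missing when
  `R0 = 0` or `|λ - 1| < 1e-10` (the ratio is indeterminate at
  stationarity); species-level averaging skips missing values.
* **Age schedules**: survivorship `lx` and fertility `mx` are obtained
  age-from-stage by iterating a cohort that starts in the first stage
  (`n_x = U^x e1`, `lx = 1'n_x`, `mx = 1'F n_x / lx`), truncated at the
  first age with `lx < 1e-7` or at age 1000.
* **Survivorship-curve shape** (Keyfitz entropy)
  `H = -Σ lx log lx / Σ lx` over positive entries: below 1 leans
  Type I, near 1 Type II, above 1 Type III. Reported as a continuous
  value, not a categorical label.
* **Degree of iteroparity** (Demetrius entropy) `S = -Σ p log p` with
  `p ∝ lx·mx`: zero for semelparity, growing as reproduction spreads
  over ages.
* **Age at maturity**: expected years to first entry into any
  reproductive stage (a stage whose `F` column has a positive entry),
  starting from the first stage, conditional on ever maturing. Computed
  from the absorbing chain via the Doob h-transform of the
  juvenile-to-juvenile block of `U`.
* **Mature life expectancy**: expected remaining lifetime (column-sum
  convention) averaged over the distribution of entry stages of
  first-passers into the reproductive set.
* **Mean sexual reproduction** `φ`: mean over all stage columns of the
  `F` column sums. **Progressive growth** `γ`: unweighted mean over
  columns 1..s-1 of the below-diagonal `U` mass. **Retrogressive
  growth** `ρ`: unweighted mean over columns 2..s of the
  above-diagonal mass. The last (first) column is excluded for γ (ρ)
  because progression (retrogression) is undefined there; for `s = 1`
  both are 0. Stable-distribution-weighted averaging is available
  behind a flag but unweighted means are the default.

Clonal recruitment `C` enters `A` for eigen-analysis and elasticities
but is excluded from recruitment-based metrics (`φ`, `mx`, `R0`,
fecundity) by default, since recruitment is read as sexual fecundity; a
switch (`include_clonal_recruitment`) folds `C` into recruitment for
sensitivity analyses.

## Juvenile/adult collapse

Stage structures differ wildly across species, so stage-specific
survival is standardized by collapsing each model to two classes:
juveniles (all stages before the first reproducing stage) and adults
(the first reproducing stage and everything after, including
post-reproductive stages). The collapse of a matrix `M` weights donor
stages by their stable-distribution share:

    M2[I, J] = Σ_{i∈I, j∈J} M_ij w_j / Σ_{j∈J} w_j.

Applied to `A` this preserves `λ` exactly (the collapsed stable
distribution is the classwise sum of `w`), which is the reason
stable-distribution weighting was chosen over plain averaging; the
property is verified to 1e-8 relative on hundreds of random models.

From the collapsed survival matrix, juvenile survival `sJ` and adult
survival `sA` are the class column sums (stasis + progression +
retrogression out of the class). Average fecundity `f̄` assumes a
post-reproductive census: per-stage fecundity is recruitment divided by
parental survival (`f_j = ΣF_ij / ΣU_ij`), then averaged over adult
stages with `w` weights. A reproducing column with zero parental
survival makes `f̄` missing (flagged, species excluded from analyses
using it).

Elasticities of juvenile and adult survival come from the elasticity
matrix of the collapsed `A2 = U2 + F2`
(`E_ij = (A2_ij/λ)(v_i w_j)/(v·w)`), with each element's elasticity
attributed to survival in proportion to the survival share
`U2_ij / A2_ij`; `eJ` collects the juvenile column, `eA` the adult
column. This collapsed-matrix convention (rather than summing
full-matrix element elasticities over class blocks) is the documented
choice; the two need not coincide.

Models whose first stage reproduces have no juvenile class; their five
collapse metrics are missing and the species is excluded from analyses
that need them (counts logged).

## Dataset assembly

Matrices are retained when they carry fecundity information (`F` not
all zero), split validly into `U/F/C` and have an annual time step.
Within a species, individual population matrices are preferred; mean
matrices are used only when no individual ones exist, and pooled
matrices only as a last resort (mean before pooled is the documented
tie-break). Species-level metrics are missing-aware arithmetic means
over retained matrices. IUCN statuses are coded LC=1, NT=2, VU=3,
EN=4, CR=5; other tokens (DD, NE, EW, EX, unknown) mark a species
unassessed — excluded from modeling but kept in the per-taxon coverage
table.

## Importance screen

A regression forest (1000 trees, mtry=4 candidate predictors per node,
variance-reduction splits, minimum node size 5, 0.632 subsampling
without replacement) is fit to species-mean metrics with the ordinal
rank as a continuous response. Conditional permutation importance is
the mean over trees of the out-of-bag MSE increase when a predictor is
permuted within strata defined by that tree's split points on
covariates correlated with it (|Pearson r| ≥ 0.2). A predictor is
selected when its importance is at least twice the magnitude of the
most negative importance (the empirical scale of random variation);
with no negative importance the threshold falls back to twice the
smallest positive value. Species with any missing metric are dropped
from the screen and logged.

The splits are CART-style rather than conditional-inference
(association-test) splits; the conditional-permutation semantics are
retained. The error measure is MSE: the response is treated as
continuous throughout, so a classification count is not well defined
without an arbitrary rounding rule, and rounding was found to cripple
the screen's power on correlated metrics.

**Known limitation.** At small sample sizes the selection rule is
anti-conservative. Out-of-bag rows share each dataset's realized
spurious associations with the training rows, so averaging over many
trees converges each importance to a small positive dataset-level
quantity while the noise floor that sets the threshold (the most
negative value) shrinks; with 14 predictors and ~40 species the
luckiest predictor clears the threshold in roughly half of pure-noise
datasets. Strongly correlated predictors add an off-manifold
permutation bias that per-tree strata on ~15 out-of-bag rows cannot
fully remove. Users should read the selected set as a shortlist for
the regression stage, not as a calibrated test; the regression stage
is where effects are quantified and tested.

## Phylogenetic regression

Residual covariance under Brownian motion is `C_ij` = shared
root-to-tip path length, computed from tip depths and patristic
distances. Pagel's lambda scales the off-diagonal entries; `λ_p` is
estimated by REML (ML available) over a 0.01-step grid on [0, 1]
refined by bounded scalar minimization (tolerance 1e-6). The [0, 1]
cap keeps the covariance positive definite on any tree. Coefficients
use the GLS normal equations via Cholesky whitening; standard errors
from `σ̂²(X'V⁻¹X)⁻¹` with two-sided t-tests on `n - p` degrees of
freedom. Predictors are standardized (mean 0, variance 1) before the
design — including interaction products — is built.

When several tree samples are supplied, a consensus is built by
averaging patristic distance matrices, estimating a topology by
neighbor joining and re-fitting branch lengths by nonnegative least
squares against the mean distances, then midpoint rooting. A single
input tree is used as-is.

Model reduction starts from all interactions among the selected
predictors (orders trimmed from the top if `n` cannot support the full
design) and repeatedly removes the least significant interaction with
`p ≥ 0.05`, highest order first, refitting after each removal; main
effects are never removed, and a lower-order interaction is not
removed while a significant higher-order term contains it. Variance
explained is `1 - var(raw residuals)/var(response)` with `n-1`
denominators — raw, not phylogenetically whitened, residuals, matching
the definition literally.

## Synthetic data

The generator emulates the joined inputs with known truth:

* **Matrices**: fast or slow archetypes draw per-stage survival,
  progression fraction and adult fertility from overlapping uniform
  ranges (fast: juvenile survival 0.2–0.8, adult survival 0.3–0.85,
  progression 0.3–0.8, fertility 1–8/year; slow: juvenile survival
  0.4–0.95, adult survival 0.6–0.98, progression 0.05–0.4, fertility
  0.1–2.5/year), a small retrogression (≤ 0.05), recruitment into the
  first stage from the last ⌈s/2⌉ stages. The ranges overlap
  deliberately: disjoint ranges were found to produce metric
  correlations above 0.95, a degenerate regime unlike real comparative
  data, in which no multi-trait analysis is informative. Column sums
  respect the survival draw by construction, so every draw is valid.
  Within-species replicate matrices apply multiplicative log-normal
  jitter (sd 0.1) with renormalization.
* **Phylogeny**: a pure-birth (Yule) tree simulated lineage-by-lineage
  with exponential waiting times, ultrametric by construction.
* **Statuses**: a latent endangerment score `g = Z_std β + ε` on the
  standardized true species-mean metrics, with
  `ε ~ N(0, σ² (λ_true C_corr + (1 - λ_true) I))` — exactly the
  residual family the PGLS estimator assumes, so recovery experiments
  are well posed. Ranks 1–5 are empirical quintiles of `g` (hence
  near-uniform by construction); a configurable fraction of species is
  left unassessed (token NE). Default conditions: 60 species, 2–6
  stages, half fast, 1–3 matrices per species, `λ_true = 0.5`,
  `σ = 1`, birth rate 1.

What the generator does **not** emulate: taxonomic imbalance and real
COMPADRE stage-label diversity, phylogenetic signal in the metrics
themselves (archetypes are assigned independently of the tree),
non-annual census intervals, and measurement error in matrix entries
beyond the log-normal jitter. Passing recovery tests therefore show
the pipeline is correct and calibrated under its own assumptions, not
that real data satisfy those assumptions.

## Study sizes used by the validation suite

Property checks use 500–1000 random models; the first-passage oracle
uses 20 models × 100 000 simulated individuals (agreement within 3
Monte-Carlo standard errors); PGLS recovery uses 100 replicates on
200-tip trees (true `λ_p = 0.7`, β = (1, 0.5)); screen operating
characteristics use 20 datasets of 40 species × 14 iid predictors per
condition; end-to-end recovery uses 20 datasets of 100 species with
standardized slopes −1.6 (age at maturity) and +1.4 (juvenile
survival), chosen by a prior power analysis so that the two-trait
contrast — the traits correlate ~0.6–0.8 along the fast–slow axis — is
detectable through the screen.

## Numerical details and degenerate inputs

Survival column-sum slack 1e-6; spectral radius of `U` must be below
1 − 1e-12 for the fundamental matrix; elasticity normalization holds
to 1e-10; collapse eigenvalue preservation to 1e-8 relative; lambda
grid step 0.01 with 1e-6 refinement tolerance. Ties and degeneracies:
`λ = 1` makes generation time missing rather than ±∞; reproduction
with zero parental survival flags fecundity missing; a first-stage
reproducer has no juvenile class and misses all five collapse metrics;
constant predictors are rejected at design construction; a constant
response makes every tree a stump and every importance exactly zero.
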