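# Methods

## The residual normalization framework

Observed log-scale expression over n subjects and g genes, collected in a
matrix Y (subjects × genes), is modeled as a Gaussian whose mean depends
linearly on covariates:

    Y = F·beta + Z·B + E

where F (n × m) holds **known** subject-level covariates (sequencing depth,
per-subject GC bias, per-subject gene-length bias, …), Z (n × k) holds
**hidden** covariates to be inferred, beta and B are their per-gene effects,
and E is i.i.d. Gaussian noise. Normalized ("true") expression is the
residual after subtracting the estimated covariate effects. Working in log
space with a Gaussian likelihood keeps every estimator in closed form, and
the main downstream analysis (Spearman-based eQTL scanning) depends only on
ranks, so count-level likelihoods would buy little.

Three classical special cases are provided in `hcpnorm.normalize`:

* **known only** — ridge regression, beta = (FᵀF + λI)⁻¹FᵀY, residual
  Y − F·beta. log-RPKM is the degenerate member of this family in which
  depth and length receive the same coefficient for every gene.
* **hidden only** — truncated SVD: remove the best rank-k approximation
  (Eckart–Young), i.e. the top k principal components.
* **known + hidden** — alternate ridge on Y − Z·W and SVD on Y − F·beta
  until the joint penalized objective stabilizes; iteration 1 is exactly
  the two-step "ridge then SVD" scheme.

## HCP: hidden covariates with prior

The contributed model keeps the factorization Y ≈ Z·B but places a Gaussian
prior on the hidden covariates centered on *linear combinations of the known
covariates*, Z ~ N(F·U, 1/λ1). Minimizing the penalized negative log
likelihood gives

    min_{Z,B,U}  ‖Y − Z·B‖²_F + λ1‖Z − F·U‖²_F + λ2‖B‖²_F + λ3‖U‖²_F.

The objective is block-convex, and each block has a closed-form exact
minimizer; we cycle U → Z → B:

    U ← (FᵀF + (λ3/λ1)·I)⁻¹ Fᵀ Z
    Z ← (Y·Bᵀ + λ1·F·U)(B·Bᵀ + λ1·I)⁻¹
    B ← (Zᵀ·Z + λ2·I)⁻¹ Zᵀ Y

Note the λ3/λ1 factor in the U update: the prior term carries λ1, so the
exact minimizer of the *joint* objective rescales the ridge on U. Writing
the update with a bare λ3 is only correct when λ1 = 1; we use the exact
form so the objective is provably non-increasing at every single update
(asserted in the tests on random instances). A fixed sweep order is used
purely for reproducibility — block convexity makes any order valid.

**Initialization.** U⁰ is standard normal scaled by 1/√m from a seeded
generator and Z⁰ = F·U⁰, so the start lies on the prior manifold and the
fit is bit-reproducible given the seed. **Convergence** is declared when the
relative objective change over a sweep drops below `tol` (default 1e-6,
`max_iter` 500). The objective is quite flat near a solution; analyses that
need tight fixed points (e.g. verifying normal equations) should use
tol ≤ 1e-12.

**Residual.** Normalized expression is Y − Z·B. The known covariates act
only through the prior on Z; no separate F·beta term is subtracted. This
matches the view that the removed artifact is the hidden-covariate
component, with F serving as side information about what artifacts look
like.

**Limits.** λ1 → ∞ forces Z into the column space of F (a ridge-like
known-covariates-only method); with F absent the λ1/λ3 terms drop and the
model becomes a ridge-penalized rank-k factorization whose optimum is the
truncated SVD as λ2 → 0 (`hcp_no_covariates`).

**Choosing parameters.** k = 20 and λ = (1, 1, 1) are defaults, not
recommendations: the intended procedure is cross-validation on the
downstream task (e.g. maximize cis-eQTL discoveries on a held-out subset of
genes, then apply that setting to all genes). The λ2/λ3 ridge penalties
matter mostly for conditioning; λ1 is the scientifically meaningful dial
between "remove the biggest trends" (small λ1) and "remove only
covariate-like patterns" (large λ1).

**Variance explained by known covariates.** `variance_explained_by_known`
regresses each fitted hidden covariate Z·j on F (OLS with intercept) and
reports per-factor R² plus an overall value weighting each factor by its
contribution ‖B_j·‖² to the removed matrix. With `nonlinear=True`, F is
augmented with squares and pairwise products to capture non-linear
combinations of the known covariates.

## Known technical covariates

`hcpnorm.covariates` builds the standard three subject-level covariates:
total mapped reads (sequencing depth); per-subject GC bias, the Pearson
correlation between a subject's per-gene log counts and per-gene percent
GC; and per-subject length bias, the same correlation against gene length
in bp. Pearson correlation is used because the quantity of interest is the
per-subject *linear* variation in log counts explainable by GC/length. The
correlations are computed on raw log counts by default (a flag accepts any
log-scale expression, e.g. log-RPKM). Covariate columns are standardized by
default so penalties act on comparable scales.

## cis-eQTL evaluation

SNPs are paired with genes whose TSS lies within 100 kb (boundary
inclusive); a SNP inside several genes' windows is assigned only to the
closest TSS, with equidistant ties broken by lower TSS then lexicographic
gene id (deterministic). Per pair, Spearman rho is computed over subjects
with observed dosage (mid-ranks for ties; pairwise-complete subjects;
monomorphic SNPs and pairs with <3 informative subjects are dropped and
logged). Two-sided p-values use the t-approximation for n ≥ 8 and the exact
permutation null (full enumeration) below that. Multiple testing is
controlled by Benjamini–Hochberg step-up over all tested pairs
(statsmodels), and discoveries are reported at 1/5/10% FDR at both pair and
unique-gene level. Gene-level p-values, used for cross-dataset consistency,
are the minimum over the gene's tested cis-SNPs; consistency between two
result sets is the Spearman correlation of their p-value vectors on shared
keys with a Fisher-z 90% CI.

## Co-expression evaluation

Networks are pairwise |Pearson| between gene columns of the residual,
optionally raised to a soft-threshold power (as in weighted co-expression
network practice). Gene function terms are filtered to a size window
(default 30–300) after removing uncurated (IEA) annotations — the order
matters and is tested. Prediction uses label spreading: solve
(I − α·S)f = (1 − α)y with S the symmetrically degree-normalized weights,
y ∈ {+1, −1, 0}; isolated nodes fall back to (1 − α)y. Accuracy is the
mean area under the precision–recall curve (step interpolation, via
scikit-learn's average-precision) over terms, in stratified 5-fold CV where
held-out genes get label 0 and are scored against all non-annotated genes
as negatives.

On dense correlation networks from small subject panels (n ≈ 60), a
background of |r| ≈ 0.8/√n noise edges carries as much total weight as the
module edges; with α near 1 the propagation then homogenizes scores and the
AUP loses discrimination regardless of signal. The default α = 0.95 is kept
for compatibility with large/sparse networks, but the benchmark scenarios
operate at α = 0.5 with soft-threshold power 6, which restores sensitivity
at these panel sizes.

## Synthetic data and the benchmark scenarios

`hcpnorm.synthetic` draws data from the framework's own generative story:
Y = F·beta + Z·B + modules + noise with Z = F·U + factor noise. Defaults
put the hidden confounder at roughly 50–75% of per-gene variance — the
broad-trend regime where normalization matters — and set the factor noise
so the known covariates explain ~50% of each hidden factor's variance
(the middle of the 35–75% range typical of real panels). Expression,
genotype, annotation and label streams derive from separate seeded
sub-streams, so regenerating one leaves the others bit-identical.
Genotypes are independent Binomial(2, maf) dosages with SNPs placed inside
disjoint 100 kb cis windows (TSS spacing 1 Mb); no linkage disequilibrium
is simulated. Planted cis effects add effect × dosage to one cis SNP per
selected gene. Function terms sample a configurable purity of their genes
from one module.

The benchmark scenarios in `hcpnorm.scenarios` fix the study conditions:

* **confounded eQTL** — n = 60 subjects, 80 genes × 2 cis SNPs, cis effects
  (size 1.0) on 40% of genes under a 2-factor broad confounder; methods
  compared at 10% FDR.
* **module co-expression** — n = 60, 200 genes, five 30-gene modules
  (within-module share ≈ 20% of variance) under the same confounder class;
  function terms of 15–25 genes at 0.9 purity anchored on modules.
* **null calibration** — pure-noise expression, 200 cis pairs, 100
  replicates; the false-discovery proportion at nominal 10% is compared to
  0.10 plus three Monte-Carlo standard errors.

Method operating points are the standard ones for ~60-subject panels:
SVD removes k = 10 components, HCP uses k = 20 factors, and the HCP
penalties are fixed at λ = (20, 5, 1) for both tasks — a single setting
standing in for per-task cross-validation, chosen so the prior is strong
enough that narrow, covariate-unrelated structure (the modules) is not
worth removing while broad confounding still is. Problem sizes are chosen
so the full benchmark suite runs in well under a minute on one CPU.

What these scenarios do **not** emulate: count-level sampling noise
(expression is generated directly on the log scale; a Poisson emission is
available separately for exercising the preprocessing path), linkage
disequilibrium, overlapping cis windows, non-Gaussian biological variation,
realistic GO term overlap, and hub-gene architecture. Passing benchmarks
therefore demonstrates correctness of the estimators and the qualitative
behavior of the methods in the regime the model assumes, not performance on
any real cohort.

## Numerical conventions

* Matrices are subjects × genes everywhere; labels are validated.
* Gene standardization uses sample SD (ddof = 1); constant genes are zeroed
  (not dropped) so gene indices stay aligned across methods, and recorded.
* SVD signs are fixed (largest-|·| element of each left component positive)
  for reproducible output.
* Genes are standardized before factor-removal methods at the pipeline/CLI
  level; the linear-algebra ops themselves do not silently transform input.
* Missing values in expression/covariates are rejected (the model has no
  missing-data mechanism); missing dosages are handled pairwise-complete.
* p-values are floored at the smallest positive float so BH input stays in
  (0, 1].
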