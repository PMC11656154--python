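# Methods

This note records the model `sumstatsim` implements, the conventions and
defaults it fixes, and the design choices made where more than one
reasonable construction exists. It states no empirical result beyond what
the test suite and `scripts/acceptance.py` compute.

## Trait model

Traits `Y₁…Y_K` follow a linear structural equation model on a DAG,
`Y = D_dirᵀ Y + δ`, where `D_dir[k,k′]` is the direct effect of trait k on
k′ per SD of each trait and `δ_k = G_dir,k + E_dir,k` sums the trait's
direct genetic and direct environmental components. Direct genetic
components are mutually independent and independent of the environment;
direct environmental components may be correlated. Every trait has total
variance 1 — inputs implying anything else are rejected, not renormalized.

Acyclicity is checked twice: a topological sort of the nonzero pattern
(clear error message) and, numerically, singularity of `I − D_dir` or a
nonzero diagonal of the total-effects matrix
`D_tot = D_dir (I − D_dir)⁻¹`, whose entry (k,k′) equals the sum over all
directed paths k→…→k′ of the products of direct effects.

### Heritability decomposition

With `VG_dir,k` the variance of trait k's own genetic component, the
trait-mediated (indirect) genetic variance is
`VG_ind,k = Σ_l D_tot[l,k]² VG_dir,l`, because the independent direct
genetic components reach trait k through total paths. Hence

```
h² = (I + D_tot∘²)ᵀ VG_dir
```

(elementwise square), solved for `VG_dir` by one linear solve. Note the
elementwise square applies to the **total** effects matrix: a formulation
squaring the direct effects instead is inconsistent with the definition of
`VG_ind` whenever a path of length ≥ 2 exists (for the worked 3-trait DAG
it under-supplies trait 3's direct variance and the realized heritability
misses its target by ~2%, which the Monte-Carlo test in `test_sem.py`
resolves decisively). A negative solution entry means a downstream trait
inherits more genetic variance than its target heritability allows; this
raises an error naming the trait.

### Environmental covariance

Using `I + D_tot = (I − D_dir)⁻¹`, the trait covariance is
`Cov(Y) = (I + D_tot)ᵀ [diag(VG_dir) + Σ_E] (I + D_tot)`. Three input modes
fix `Σ_E`, the covariance of direct environmental components:

* **default** — independent components; variances solve
  `(I + D_tot∘²)ᵀ v_E = 1 − h²` so every trait variance is exactly 1;
* **observational correlation `R_obs`** — exact inversion
  `Σ_E = (I − D_dir)ᵀ R_obs (I − D_dir) − diag(VG_dir)`, no iterative
  fitting; if the implied `Σ_E` has an eigenvalue below −1e−10 the target
  is infeasible and an error is raised (we reject rather than project to
  the nearest feasible matrix, so the user's model is never silently
  changed); eigenvalues in (−1e−10, 0) are clipped to 0;
* **environmental correlation `R_E`** — the environmental SDs are solved
  trait-by-trait in topological order; each trait contributes one scalar
  quadratic with a unique nonnegative root when feasible.

## LD representation

An LD pattern is an ordered list of within-block correlation matrices with
one allele frequency per position (blocks accepted if the smallest
eigenvalue is ≥ −1e−8, then symmetrized and clipped). Patterns are tiled to
`J` variants by repeating the block list, possibly fractionally; a
partially used block becomes its leading principal submatrix, which remains
a valid correlation matrix, and allele frequencies recycle in lockstep with
positions. Tiles are independent copies, so long-range LD across blocks
cannot be represented. Built-in generators: `identity` (no LD, the
default) and `ar1(size, ρ)` with entries `ρ^|i−j|`.

Utilities: dense submatrix extraction; greedy LD pruning by ascending
p-value (ties broken by lower variant index; a variant is kept iff its r²
with every kept variant is below the threshold, default 0.1, with an
optional p-value cutoff); proxy lookup returning all block-mates with
r² ≥ threshold. Variant indices are 0-based in code; written tables use
1-based ids `snp_1…snp_J`.

## Effect simulation

Variant j is causal for trait k with probability `pi[j,k]` (scalar, per-trait
vector, or J×K matrix; 0/1 entries select deterministically). Causal
standardized effects `γ̃ = γ·√(2f(1−f))` are drawn from a scale-family
handle `(n, total_variance, variant_info, rng) → n draws` whose expected
sum of squares equals the requested total. The handle is invoked with
`total_variance = VG_dir·n_realized/E[count]` (expected count
`Σ_j pi[j,k]`), so each draw carries expected square `VG_dir/E[count]` —
for scalar π and the default normal family this is the classical
`N(0, VG_dir/(πJ))` draw. Built-ins: normal, scale mixture of normals
(component variances fix relative scales), and fixed-up-to-a-scalar;
custom handles receive the per-variant annotation table with an appended
`AF` column, enabling annotation-dependent architectures such as
LDAK-style frequency weighting. A trait whose causal-indicator draw comes
up empty while `VG_dir > 0` raises an error rather than silently
resampling, so replicate counts stay honest.

With `h2_exact`, each trait's column is rescaled by one scalar so the
LD-aware quadratic form `γ̃ᵀRγ̃` (computed blockwise) equals `VG_dir`
exactly; we normalize the **direct** component and report the realized
total heritability `β̃(joint)ᵀRβ̃(joint)` rather than forcing it. Direct
effects propagate per variant as `β̃(joint) = (I + D_totᵀ)γ̃` and
`β̃(marg) = R β̃(joint)` per tiled block.

## Sampling summary statistics

Effect estimates are drawn on the standardized scale per tiled block:
`b̃ = R β̃(joint) + N^{-1/2} ∘ (L E Mᵀ)` with `L Lᵀ = R` (symmetric
eigendecomposition, eigenvalues clipped at 0, factor cached per distinct
source block so tiling shares the linear algebra), `M Mᵀ = C` and i.i.d.
standard-normal `E`; dividing by `√(2f(1−f))` gives per-allele `β̂`. The
cross-trait correlation is `C[k,k′] = N_{k,k′}/√(N_k N_k′) · ρ_{k,k′}`
with `ρ` the model-level population trait correlation (not the realized
correlation of any draw). Traits with zero sample size are dropped before
any factorization and get no output columns. True standard errors are
`s = 1/√(N·2f(1−f))` under the unit-variance convention.

### Standard-error estimates

The regression SE satisfies `ŝ² = SSR/((N−2)·SSX)`; conditional on the
genotypes, classical OLS gives `SSR ~ σ_r² χ²_{N−2}` independent of `SSX`,
with `σ_r²` the population residual variance of the marginal regression.
We draw both pieces from their sampling distributions:

* `σ_r² = v_Y − β̃(marg)²`, where `v_Y = 1 − h²_target + h²_realized` is
  the variance the phenotype actually has under the realized effect draw —
  a finite draw's heritability differs from the target, and the SE of a
  GWAS on those effects scales with the realized variance;
* one `χ²_{N−2}` draw per trait, shared by all of the trait's variants
  (the phenotypic sum of squares dominates SSR), coupled across
  overlapping traits by a Gaussian copula with correlation `F·ρ²`
  (`F = N_{k,k′}/√(N_k N_k′)`; squared phenotypes of shared samples
  co-vary as ρ²);
* `SSX` per variant from a Satterthwaite-matched scaled χ² with the exact
  binomial(2, f) moments — mean `(N−1)v` and variance `N(μ₄ − v²)`,
  `μ₄ = 16f⁴q² + 2fq(1−2f)⁴ + 16f²q⁴` — since the χ²_{N−1} shape implied
  by normal genotypes has the wrong variance (a factor ~2 off at both
  common and rare frequencies); within a block, SSX values are tied by an
  `R∘²` copula (squares of correlated genotypes correlate ≈ r²), and
  across overlapping traits by an `F` copula (the studies share
  genotypes).

`z = β̂/ŝ` and two-sided normal p-values complete the tables. The
cross-variant and cross-trait dependence of `ŝ` under this scheme is an
approximation by construction; its adequacy is assessed empirically by the
equivalence harness, not asserted.

## Individual-level oracle

Genotypes are generated haplotype-wise with the latent-Gaussian threshold
construction: per block, latent pairwise correlations are solved by
bracketed root finding on the bivariate-normal orthant probability so the
allele-indicator correlations match the target LD (tolerance 1e−6;
infeasible targets are clipped to the nearest achievable value with a
warning); the assembled latent matrix is repaired by eigenvalue clipping if
not jointly PSD — a known approximation of this construction — and its
factor is cached per source block. A genotype is the sum of two independent
haplotypes, giving exact Hardy–Weinberg marginals. Note that an indicator
correlation between variants with very different allele frequencies has a
restricted feasible range; LD matrices estimated from real genotypes
satisfy this automatically, and synthetic fixtures in this package are
built through the forward threshold map so they do too.

Phenotypes follow the additive model in its structurally equivalent form:
per-sample direct components `δ = G̃γ̃ + E_dir`, `E_dir ~ N(0, Σ_E)`,
propagated as `Y = δ(I + D_tot)`; genotypes are standardized with the true
frequency (centered by 2f, scaled by √(2f(1−f))), not sample estimates.
Sample overlap is realized as one union cohort in which each trait pair
gets a dedicated pool of `N_{k,k′}` shared samples and traits are topped up
with exclusive samples; this reproduces all pairwise overlaps exactly with
no three-way overlap and requires `N_k ≥ Σ_{k′≠k} N_{k,k′}` (an error
otherwise). Marginal regressions are the exact textbook formulas per
trait membership; monomorphic variants yield missing estimates with a
warning. The three resampling modes (genotypes only / phenotypes only for
given genotypes / both) mirror the summary-statistic workflow, and
alternative genotype generators can be substituted behind the same
contract.

## The equivalence harness

`validate_equivalence` fixes one draw of true effects, generates `n_reps`
summary-statistic realizations per method (direct vs. individual-level),
and compares per-coordinate means and SDs, all pairwise covariances of
`β̂` and `ŝ`, and Q–Q slopes. Its canonical configuration
(`accuracy_experiment`) uses ten variants in one LD block built by pushing
a latent AR1(0.9) through the threshold map at frequencies drawn once from
U(0.25, 0.75); two traits with no causal connection, disjoint causal sets
(positions {1, 6} and {3, 8, 10}, 1-based) each explaining 0.4% of trait
variance; observational correlation 0.7; GWAS sizes 8000 and 10000 with
2000 shared samples. The individual-level arm is guarded by a
`J·max(N) ≤ 2e8` cap.

Each moment comparison is scored as a z-statistic (difference over the
combined Monte-Carlo SE — for a covariance, `Var ≈ (σ²σ′² + cov²)/n`) and
flagged beyond 3. With ~460 comparisons a correct simulator still produces
a few 3-SE excursions by chance, so the verdict allows flags up to the
99.9% binomial envelope of the nominal 3-SE false-positive rate; the
negative control (`assume_no_overlap=True`, which silently drops the
overlap from the direct arm) exceeds the envelope by roughly an order of
magnitude. Q–Q slopes are computed per trait and statistic on
pooled-standardized samples (each coordinate centered and scaled by its
pooled mean/SD, quantiles restricted to the 5–95% range) because
per-coordinate slope estimates at these replicate counts carry several
percent of Monte-Carlo noise; the acceptance band is [0.95, 1.05] at 1000
replicates per method. The tests run the harness at 1000 replicates, a
size chosen so the whole experiment completes in well under a minute on
one core.

## Defaults and numerical conventions

| Quantity | Default | Notes |
|---|---|---|
| LD | none (identity) | pattern optional |
| Allele frequencies | U(0.05, 0.95) draws | when no pattern/frequencies given |
| Causal probability `pi` | 0.1 (config) | explicit argument in the API |
| Effect family | normal | point-normal jointly with `pi` |
| Pruning r² threshold | 0.1 | p-value cutoff off by default |
| Block PSD tolerance | eigenvalue ≥ −1e−8 | then clipped at 0 |
| SEM feasibility tolerances | 1e−10 (PSD), 1e−8 (unit variance) | |
| Latent-correlation solve | 1e−6 | bracketed root finding |
| RNG | one root seed → named substreams | effect draws reproducible independently of downstream stages |

Output tables are tab-separated with 17-significant-digit floats (exact
round trip through the package reader), LF line endings, gzip by file
extension.

## What the synthetic conditions do and do not show

The generator produces unrelated samples from one homogeneous population,
simple-regression GWAS with no covariates, no population-structure or
relatedness confounding, continuous traits only, and block LD with no
long-range dependence. Passing tests therefore demonstrate correctness of
the sampling mathematics under the stated model — not robustness to
structure, relatedness, binary traits on the liability scale, or
interaction effects, all of which are outside the model's scope.

## Known limitations

* Binary traits / liability models are not supported.
* The `ŝ` dependence structure is approximate (see above); marginals and
  the leading cross-correlations are validated empirically.
* Pairwise-overlap realization cannot express designs that require
  three-way sample overlap.
* Very strong LD between variants with very different allele frequencies
  is infeasible for binary genotypes; the individual-level generator clips
  such targets (with a warning), so equivalence holds only for achievable
  LD patterns.
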