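# sumstatsim

Direct simulation of GWAS summary statistics for multiple causally related
traits, with linkage disequilibrium, flexible effect-size distributions, and
arbitrary sample overlap between studies.

## Who this is for

Methods that consume GWAS summary statistics — Mendelian randomization,
genetic-correlation and heritability estimators, polygenic risk scores,
colocalization — need realistic benchmark data. Simulating genotypes and
phenotypes for hundreds of thousands of individuals and then running millions
of marginal regressions is slow and storage-hungry. `sumstatsim` instead
samples the effect estimates directly from their asymptotic distribution,
which is orders of magnitude cheaper and, as the package's own validation
harness demonstrates, distributionally indistinguishable from full-data
simulation.

## The model

For a continuous trait with unit variance, the marginal effect estimates of
`J` biallelic variants in Hardy–Weinberg equilibrium follow approximately

```
β̂ ~ N(S R S⁻¹ β(joint),  S R S)
```

where `R` is the LD (genotype correlation) matrix, `β(joint)` are the causal
effects of the additive model `Y = Σⱼ βⱼ(joint) Gⱼ + ε`, and
`S = diag(sⱼ)` with `sⱼ = 1/√(N·2fⱼ(1−fⱼ))` for sample size `N` and allele
frequency `fⱼ`.

Multiple traits are tied together by a linear structural equation model over
a DAG: a direct-effects matrix `D_dir` with total effects
`D_tot = D_dir (I − D_dir)⁻¹`, heritabilities decomposed into direct and
trait-mediated parts via `h² = (I + D_tot∘²)ᵀ VG_dir`, and per-variant joint
effects `β(joint) = (I + D_totᵀ) γ`. Overlapping GWAS samples induce
cross-study estimate correlation `N_{kk'}/√(N_k N_k') · ρ_{kk'}` where `ρ` is
the population trait correlation. Standard-error *estimates* `ŝ` are also
simulated (most direct samplers return only the true standard error), by
drawing the residual and genotype sums of squares of the underlying
regression from their sampling distributions.

An individual-level simulator (latent-Gaussian threshold genotypes, SEM
phenotypes, exact textbook regressions) serves as the validation oracle and
as a test bed for PRS workflows.

## Worked example

An MR-style simulation: exposure X, outcome Y, and a heritable confounder U
with X→Y = 0.3, U→X = 0.4, U→Y = 0.5. We need no summary statistics for U,
so its sample size is zero; the exposure and outcome GWAS (40k and 60k
samples) share 10k individuals.

```python
import numpy as np
import sumstatsim as ss

D = np.array([[0.0, 0.3, 0.0],    # traits ordered X, Y, U
              [0.0, 0.0, 0.0],
              [0.4, 0.5, 0.0]])
n = np.array([[40000, 10000, 0],
              [10000, 60000, 0],
              [0,     0,     0]])
pattern = ss.make_ld_pattern(("ar1", 50, 0.7), np.full(50, 0.4))
sim = ss.simulate(D, [0.3, 0.3, 0.3], n, 1000, 0.05,
                  ld_pattern=pattern, seed=1)

print(sim.model.d_tot[0, 1])                  # 0.3  (total X→Y effect)
print(np.round(sim.model.trait_correlation, 3))
print(sim.sumstats.trait_labels)              # ['trait_1', 'trait_2'] — no U
print(sim.sumstats.to_frames()["trait_1"].head())
```

prints the population trait correlation implied by the SEM,

```
[[1.    0.5   0.4 ]
 [0.5   1.    0.62]
 [0.4   0.62  1.  ]]
```

and the exposure's summary-statistic table (per-allele scale; `SE` is the
simulated standard-error estimate, `SE_TRUE` the exact one):

```
  SNP  AF      BETA       SE  SE_TRUE       Z      P     N
snp_1 0.4 -0.003206 0.007197 0.007217 -0.4455  0.656 40000
snp_2 0.4 -0.005345 0.007159 0.007217 -0.7467 0.4553 40000
snp_3 0.4 -0.001804 0.007155 0.007217 -0.2521  0.801 40000
```

Selecting approximately independent exposure instruments for MR:

```python
kept = ss.ld_prune(sim.layout, sim.sumstats.p[:, 0],
                   r2_threshold=0.1, p_threshold=5e-8)
```

returns 55 variant indices whose pairwise r² stays below 0.1, ordered by
exposure p-value. `ss.resample_sumstats` re-draws GWAS noise with the same
true effects (e.g. for a three-sample MR design), and `ss.resample_inddata`
generates genotype/phenotype cohorts for PRS evaluation.

A `sumstatsim` CLI wraps the same functionality
(`simulate`, `resample-sumstats`, `resample-individual`, `prune`,
`validate`) around a YAML configuration; see `sumstatsim --help`.

## Validation

`sumstatsim.validate.validate_equivalence` replicates the accuracy
experiment behind the method: a fixed draw of true effects for ten variants
in LD and two overlapping GWAS, then 1000 summary-statistic realizations per
method — direct sampling versus genotype-level simulation with exact
regressions — compared on per-coordinate means, SDs, all pairwise
covariances, and pooled Q–Q slopes. A deliberately corrupted sampler
(overlap ignored) is flagged by the same harness.

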