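"""Sampling GWAS effect estimates and standard-error estimates.

Effect estimates for one trait follow the asymptotic model

    β̂ ~ N(S R S⁻¹ β(joint), S R S)

with ``S = diag(s_j)``, ``s_j = √(Var(Y) / (v_j N))`` and ``v_j = 2f_j(1−f_j)``.
Across traits, sample overlap couples the estimates: for variants j, j' and
traits k, k'

    Cov(β̂_{j,k}, β̂_{j',k'}) ≈ R_{j,j'} s_{j,k} s_{j',k'} · (N_{k,k'} / √(N_k N_k')) · ρ_{k,k'}

where ``N_{k,k'}`` counts the overlapping samples and ``ρ`` is the population
trait correlation.  Sampling happens on the standardized (z-like) scale per
tiled LD block: ``b̃ = R β̃(joint) + N^{-1/2} ∘ (L E Mᵀ)`` with ``L Lᵀ = R``,
``M Mᵀ = C`` and i.i.d. standard-normal ``E``; division by ``√v_j`` returns
the per-allele scale.  Block factorizations are cached per distinct source
block, so tiling a small pattern to a large genome shares the linear algebra.

Standard-error *estimates* ``ŝ`` are simulated by drawing the two sums of
squares in the textbook SE formula from their sampling distributions: a
per-trait residual sum of squares ``σ_r² χ²_{N−2}`` (shared across a trait's
variants and coupled across overlapping traits) over a per-variant genotype
sum of squares from a
moment-matched scaled χ² (matching the exact binomial(2, f) variance of the
centered genotype square, correlated within an LD block through an ``R∘²``
copula): ``ŝ² = σ_r² SSR / ((N−2)·SSX)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import GenomeLayout

__all__ = [
    "SampleDesign",
    "SummaryStats",
    "build_sample_design",
    "overlap_correlation",
    "sample_effect_estimates",
    "sample_standard_errors",
    "assemble_sumstats",
]


@dataclass
class SampleDesign:
    """GWAS sample sizes and pairwise overlaps.

    ``n_matrix`` is K×K symmetric: diagonal = per-trait sample sizes (0 means
    the trait is unobserved and gets no summary statistics), off-diagonal
    (k, k') = number of samples in both GWAS.
    """

    n_matrix: np.ndarray

    def __post_init__(self) -> None:
        N = np.asarray(self.n_matrix, dtype=float)
        if N.ndim != 2 or N.shape[0] != N.shape[1]:
            raise ValueError("n_matrix must be square")
        if not np.allclose(N, N.T):
            raise ValueError("n_matrix must be symmetric")
        if np.any(N < 0):
            raise ValueError("sample sizes and overlaps must be nonnegative")
        if not np.allclose(N, np.round(N)):
            raise ValueError("sample sizes and overlaps must be integers")
        diag = np.diag(N)
        cap = np.minimum.outer(diag, diag)
        off = ~np.eye(N.shape[0], dtype=bool)
        if np.any(N[off] > cap[off] + 1e-9):
            raise ValueError("overlap exceeds the smaller of the two sample sizes")
        self.n_matrix = np.round(N).astype(int)

    @property
    def n_traits(self) -> int:
        return self.n_matrix.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.diag(self.n_matrix)

    @property
    def observed(self) -> np.ndarray:
        """Indices of traits with a positive sample size."""
        return np.flatnonzero(self.sizes > 0)

    def restrict(self, traits) -> "SampleDesign":
        idx = np.asarray(traits, dtype=int)
        return SampleDesign(self.n_matrix[np.ix_(idx, idx)])


def build_sample_design(n, K: int) -> SampleDesign:
    """Promote a scalar / length-K vector / K×K matrix to a :class:`SampleDesign`.

    Scalar: every trait gets that size, no overlap.  Vector: per-trait sizes,
    no overlap.  Matrix: used as-is after validation.
    """
    arr = np.asarray(n, dtype=float)
    if arr.ndim == 0:
        mat = np.diag(np.full(K, float(arr)))
    elif arr.ndim == 1:
        if arr.shape[0] != K:
            raise ValueError(f"sample-size vector must have length K={K}")
        mat = np.diag(arr)
    elif arr.shape == (K, K):
        mat = arr
    else:
        raise ValueError(f"sample-size input must be scalar, length-{K} or {K}x{K}")
    return SampleDesign(mat)


def overlap_correlation(design: SampleDesign, trait_correlation) -> np.ndarray:
    """Estimate-correlation matrix ``C[k,k'] = N_{k,k'}/√(N_k N_k') · ρ_{k,k'}``.

    Computed over the observed traits only (drop zero-size traits first);
    eigenvalue-clipped to PSD if round-off pushes it slightly outside.
    """
    rho = np.asarray(trait_correlation, dtype=float)
    N = design.n_matrix.astype(float)
    sizes = np.diag(N)
    if np.any(sizes <= 0):
        raise ValueError("drop unobserved traits before computing overlap correlation")
    C = N / np.sqrt(np.outer(sizes, sizes)) * rho
    np.fill_diagonal(C, 1.0)
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < 0:
        C = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return C


def _clip_corr(mat: np.ndarray) -> np.ndarray:
    """Symmetrize and eigenvalue-clip a near-correlation matrix to PSD."""
    C = 0.5 * (mat + mat.T)
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < 0:
        C = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def _sqrt_factor(mat: np.ndarray, tol: float = -1e-8) -> np.ndarray:
    """Symmetric square-root factor with eigenvalue clipping at zero."""
    evals, evecs = np.linalg.eigh(0.5 * (mat + mat.T))
    if evals.min() < tol * max(1.0, evals.max()):
        raise ValueError("matrix is not PSD within tolerance")
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


class _BlockFactorCache:
    """Per-source-block factor cache shared across tiles (and truncations)."""

    def __init__(self, layout: GenomeLayout, transform=None):
        self._layout = layout
        self._transform = transform
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def factor(self, tiled_index: int) -> np.ndarray:
        src, size = self._layout.tiled_blocks[tiled_index]
        key = (src, size)
        if key not in self._cache:
            block = self._layout.pattern.blocks[src][:size, :size]
            if self._transform is not None:
                block = self._transform(block)
            self._cache[key] = _sqrt_factor(block)
        return self._cache[key]


def sample_effect_estimates(
    beta_marg_std: np.ndarray,
    layout: GenomeLayout,
    design: SampleDesign,
    C: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-allele effect estimates ``β̂`` (J × K_obs).

    ``beta_marg_std`` holds the standardized marginal means ``R β̃(joint)``
    restricted to the observed traits, in observed-trait column order.
    """
    beta_marg = np.asarray(beta_marg_std, dtype=float)
    J, K_obs = beta_marg.shape
    if J != layout.n_variants:
        raise ValueError("beta_marg_std must have one row per variant")
    sizes = design.sizes[design.observed].astype(float)
    if sizes.shape[0] != K_obs:
        raise ValueError("beta_marg_std columns must match observed traits")
    M = _sqrt_factor(np.asarray(C, dtype=float)).T  # right factor: E @ M has cov C
    factors = _BlockFactorCache(layout)
    b = np.array(beta_marg, copy=True)
    for t, (sl, _) in enumerate(layout.iter_blocks()):
        L = factors.factor(t)
        E = rng.standard_normal((L.shape[1], K_obs))
        b[sl] += (L @ E @ M) / np.sqrt(sizes)[None, :]
    return b / np.sqrt(layout.variant_var)[:, None]


def true_standard_errors(layout: GenomeLayout, sizes: np.ndarray) -> np.ndarray:
    """``s_{j,k} = √(1 / (N_k v_j))`` under unit trait variance."""
    v = layout.variant_var
    return 1.0 / np.sqrt(np.outer(v, sizes.astype(float)))


def _genotype_ss_moments(af: np.ndarray, n: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the genotype sum of squares Σ(g − ḡ)².

    For a binomial(2, f) genotype the centered square has fourth central
    moment μ4 = 16f⁴q² + 2fq(1−2f)⁴ + 16f²q⁴ (q = 1 − f); the sum of squares
    is asymptotically normal with mean (n−1)v and variance n(μ4 − v²).
    """
    f = af
    q = 1.0 - f
    v = 2.0 * f * q
    mu4 = 16 * f**4 * q**2 + 2 * f * q * (1 - 2 * f) ** 4 + 16 * f**2 * q**4
    return (n - 1.0) * v, n * (mu4 - v**2)


def sample_standard_errors(
    layout: GenomeLayout,
    design: SampleDesign,
    trait_correlation: np.ndarray,
    beta_marg_std: np.ndarray,
    rng: np.random.Generator,
    trait_variance: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate standard-error estimates ``ŝ`` (J × K_obs).

    The regression SE is ``ŝ² = SSR / ((N−2)·SSX)`` with residual and
    genotype sums of squares; conditional on the genotypes, classical OLS
    gives ``SSR ~ σ_r² χ²_{N−2}`` independent of ``SSX``, where
    ``σ_r² = 1 − β̃(marg)²`` is the population residual variance of the
    marginal regression.  Both pieces are drawn from those sampling
    distributions, with Gaussian copulas reproducing how overlapping
    samples tie the pieces together (``F = N_{k,k'}/√(N_k N_k')`` is the
    overlap fraction):

    * one residual ``χ²_{N_k−2}`` draw per trait — shared by all variants
      of the trait, as the phenotypic sum of squares dominates SSR — with
      cross-trait copula correlation ``F·ρ²`` (squared phenotypes of shared
      samples co-vary as ρ²);
    * ``SSX_{j,k}`` from a scaled χ² matched to the exact mean/variance of
      the binomial(2, f) genotype sum of squares, correlated within an LD
      block through an ``R∘²`` copula (squares of correlated genotypes are
      correlated) and across traits through ``F`` (overlapping GWAS share
      genotypes), independent across blocks.

    ``beta_marg_std`` carries the standardized marginal effects of the
    observed traits (they set ``σ_r²``); ``trait_correlation`` is the
    population trait correlation restricted to the observed traits.
    ``trait_variance`` is the *realized* phenotype variance per observed
    trait, ``1 − h²_target + h²_realized`` (default 1): a finite draw of
    effects carries a realized heritability different from the target, and
    the SE estimates of a GWAS on those effects scale with the variance the
    phenotype actually has.
    """
    obs = design.observed
    sizes = design.sizes[obs].astype(float)
    if np.any(sizes < 3):
        raise ValueError("SE simulation requires N >= 3 for every observed trait")
    J = layout.n_variants
    K_obs = sizes.shape[0]
    beta_marg = np.asarray(beta_marg_std, dtype=float)
    if beta_marg.shape != (J, K_obs):
        raise ValueError("beta_marg_std must be J x K_obs")
    rho = np.asarray(trait_correlation, dtype=float)
    v_y = np.ones(K_obs) if trait_variance is None else np.asarray(trait_variance, dtype=float)
    resid_var = np.clip(v_y[None, :] - beta_marg**2, 1e-6, None)
    F = design.n_matrix[np.ix_(obs, obs)] / np.sqrt(np.outer(sizes, sizes))
    np.fill_diagonal(F, 1.0)

    # per-trait residual sum of squares; cross-trait copula over F·ρ²
    Mr = _sqrt_factor(_clip_corr(F * rho**2))
    zy = Mr @ rng.standard_normal(K_obs)
    ssr = stats.chi2.ppf(stats.norm.cdf(zy), df=sizes - 2.0)

    # per-variant genotype sums of squares: R∘2 copula within blocks,
    # F copula across traits (Kronecker structure)
    Mf = _sqrt_factor(_clip_corr(F)).T
    sq_factors = _BlockFactorCache(layout, transform=lambda b: b**2)
    zx = np.empty((J, K_obs))
    for t, (sl, _) in enumerate(layout.iter_blocks()):
        Lsq = sq_factors.factor(t)
        zx[sl] = Lsq @ rng.standard_normal((Lsq.shape[1], K_obs)) @ Mf
    u = stats.norm.cdf(zx)
    mean_ss, var_ss = _genotype_ss_moments(layout.variant_af[:, None], sizes[None, :])
    # Satterthwaite: SSX ~ c·χ²_d with c·d = mean, 2c²d = var
    dof = 2.0 * mean_ss**2 / var_ss
    scale = mean_ss / dof
    ssx = scale * stats.chi2.ppf(u, df=dof)

    s2 = resid_var * ssr[None, :] / ((sizes[None, :] - 2.0) * ssx)
    return np.sqrt(s2)


@dataclass
class SummaryStats:
    """Simulated GWAS summary statistics for the observed traits.

    Per-allele scale throughout.  ``se_hat`` equals ``se_true`` when SE
    simulation is disabled.  ``z`` and ``p`` are computed from ``se_hat``.
    """

    snp: list[str]
    af: np.ndarray
    beta_hat: np.ndarray
    se_true: np.ndarray
    se_hat: np.ndarray
    z: np.ndarray
    p: np.ndarray
    trait_labels: list[str]
    sample_sizes: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return self.beta_hat.shape[0]

    @property
    def n_traits(self) -> int:
        return self.beta_hat.shape[1]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """One tidy table per trait: SNP, AF, BETA, SE, SE_TRUE, Z, P, N."""
        out = {}
        for k, label in enumerate(self.trait_labels):
            out[label] = pd.DataFrame(
                {
                    "SNP": self.snp,
                    "AF": self.af,
                    "BETA": self.beta_hat[:, k],
                    "SE": self.se_hat[:, k],
                    "SE_TRUE": self.se_true[:, k],
                    "Z": self.z[:, k],
                    "P": self.p[:, k],
                    "N": int(self.sample_sizes[k]),
                }
            )
        return out


def assemble_sumstats(
    beta_hat: np.ndarray,
    se_true: np.ndarray,
    se_hat: np.ndarray,
    design: SampleDesign,
    layout: GenomeLayout,
    trait_labels: list[str] | None = None,
    provenance: dict | None = None,
) -> SummaryStats:
    """Assemble the :class:`SummaryStats` object for the observed traits.

    Columns exist only for traits with a positive sample size; ``z = β̂/ŝ``
    and ``p`` is the two-sided standard-normal tail probability.
    """
    obs = design.observed
    beta_hat = np.asarray(beta_hat, dtype=float)
    se_true = np.asarray(se_true, dtype=float)
    se_hat = np.asarray(se_hat, dtype=float)
    if not (beta_hat.shape == se_true.shape == se_hat.shape):
        raise ValueError("beta_hat, se_true and se_hat must share a shape")
    if beta_hat.shape[1] != obs.size:
        raise ValueError("arrays must have one column per observed trait")
    if trait_labels is None:
        trait_labels = [f"trait_{k + 1}" for k in obs]
    z = beta_hat / se_hat
    p = 2.0 * stats.norm.sf(np.abs(z))
    return SummaryStats(
        snp=layout.snp_ids(),
        af=layout.variant_af.copy(),
        beta_hat=beta_hat,
        se_true=se_true,
        se_hat=se_hat,
        z=z,
        p=p,
        trait_labels=list(trait_labels),
        sample_sizes=design.sizes[obs],
        provenance=provenance or {},
    )
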