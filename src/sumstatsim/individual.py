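"""Individual-level simulation: the validation oracle and PRS test bed.

Genotypes are generated haplotype-wise with the latent-Gaussian threshold
construction: per LD block, a multivariate normal vector is binarized at
``Φ⁻¹(f_j)``; the latent pairwise correlations are solved (by monotone root
finding on the bivariate normal orthant probability) so the *allele
indicator* correlations match the target LD matrix.  A genotype is the sum
of two independent haplotypes, giving Hardy-Weinberg marginals and LD ≈ R.

Phenotypes follow the additive model ``Y = Σ_j β_j(joint) G_j + ε`` written
in its structurally equivalent form: per-sample direct components
``δ = G̃ γ̃ + E_dir`` with ``E_dir ~ N(0, Σ_E)``, propagated through the
trait DAG as ``Y = δ (I + D_tot)``.  Marginal regression summary statistics
are then exact textbook quantities, computed per trait over that trait's
membership subset of one union cohort (pairwise overlaps realized as
dedicated shared sample pools).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import sampling as smp
from .effects import compute_marginal_effects
from .ld import GenomeLayout
from .simulate import Simulation, _draw_sumstats, named_streams

__all__ = [
    "IndividualData",
    "solve_latent_correlation",
    "latent_block_correlation",
    "indicator_correlation_from_latent",
    "simulate_genotypes",
    "simulate_phenotypes",
    "build_membership",
    "regression_sumstats",
    "resample_inddata",
    "resample_sumstats",
]


def _indicator_corr_bounds(f1: float, f2: float) -> tuple[float, float]:
    """Feasible correlation range for Bernoulli(f1), Bernoulli(f2) indicators."""
    q1, q2 = 1 - f1, 1 - f2
    lo = max(-np.sqrt(f1 * f2 / (q1 * q2)), -np.sqrt(q1 * q2 / (f1 * f2)))
    hi = min(np.sqrt(f1 * q2 / (f2 * q1)), np.sqrt(f2 * q1 / (f1 * q2)))
    return lo, hi


def _bvn_cdf(h1: float, h2: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([h1, h2]))


def solve_latent_correlation(f1: float, f2: float, target_r: float, tol: float = 1e-6) -> float:
    """Latent Gaussian correlation reproducing a target allele-indicator correlation.

    Binarizing standard normals ``(Z1, Z2)`` with correlation ``ρ`` at
    thresholds ``Φ⁻¹(f1), Φ⁻¹(f2)`` gives indicators with correlation
    ``(Φ₂(h1, h2; ρ) − f1 f2) / √(f1 q1 f2 q2)``, monotone increasing in
    ``ρ``; the equation is solved by bracketed root finding.  A target
    outside the achievable range is clipped to the nearest feasible value
    with a warning.
    """
    if not (0 < f1 < 1 and 0 < f2 < 1):
        raise ValueError("allele frequencies must be in (0, 1)")
    if target_r == 0.0:
        return 0.0
    h1, h2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    denom = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))

    def indicator_corr(rho: float) -> float:
        return (_bvn_cdf(h1, h2, rho) - f1 * f2) / denom

    lim = 1.0 - 1e-9
    lo, hi = indicator_corr(-lim), indicator_corr(lim)
    if target_r <= lo or target_r >= hi:
        clipped = np.clip(target_r, lo + tol, hi - tol)
        warnings.warn(
            f"target indicator correlation {target_r:.4f} is infeasible for "
            f"f=({f1:.3f}, {f2:.3f}); clipping to {clipped:.4f}",
            stacklevel=2,
        )
        target_r = float(clipped)
    return float(
        optimize.brentq(lambda r: indicator_corr(r) - target_r, -lim, lim, xtol=tol)
    )


def indicator_correlation_from_latent(latent: np.ndarray, af: np.ndarray) -> np.ndarray:
    """Forward map: allele-indicator correlations implied by a latent Gaussian.

    The inverse of :func:`latent_block_correlation`; useful for building LD
    fixtures that are exactly achievable by binary genotypes (real LD
    matrices are frequency-compatible in this sense automatically).
    """
    Q = np.asarray(latent, dtype=float)
    af = np.asarray(af, dtype=float)
    h = stats.norm.ppf(af)
    m = Q.shape[0]
    R = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            p11 = _bvn_cdf(h[i], h[j], Q[i, j])
            denom = np.sqrt(af[i] * (1 - af[i]) * af[j] * (1 - af[j]))
            R[i, j] = R[j, i] = (p11 - af[i] * af[j]) / denom
    return R


def latent_block_correlation(block: np.ndarray, af: np.ndarray) -> np.ndarray:
    """Latent correlation matrix for one LD block (pairwise solves, PSD repair).

    Pairwise latent correlations are exact; the assembled matrix may not be
    jointly PSD, in which case it is repaired by eigenvalue clipping (the
    standard approximation of this construction) with a warning.
    """
    m = block.shape[0]
    Q = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            Q[i, j] = Q[j, i] = solve_latent_correlation(af[i], af[j], float(block[i, j]))
    evals, evecs = np.linalg.eigh(Q)
    if evals.min() < -1e-8:
        warnings.warn(
            "assembled latent correlation matrix is not PSD "
            f"(min eigenvalue {evals.min():.3g}); repairing by eigenvalue clipping",
            stacklevel=2,
        )
    if evals.min() < 0:
        Q = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        d = np.sqrt(np.diag(Q))
        Q = Q / np.outer(d, d)
        np.fill_diagonal(Q, 1.0)
    return Q


class _LatentCache:
    """Latent square-root factors per distinct (source block, size).

    Stored on the layout object so repeated genotype draws (e.g. the
    replicates of the equivalence experiment) share the pairwise solves.
    """

    def __init__(self, layout: GenomeLayout):
        self._layout = layout
        if not hasattr(layout, "_latent_factor_cache"):
            layout._latent_factor_cache = {}
        self._cache: dict[tuple[int, int], np.ndarray] = layout._latent_factor_cache

    def factor(self, tiled_index: int) -> np.ndarray:
        src, size = self._layout.tiled_blocks[tiled_index]
        key = (src, size)
        if key not in self._cache:
            block = self._layout.pattern.blocks[src][:size, :size]
            start = self._layout.block_starts[tiled_index]
            af = self._layout.variant_af[start : start + size]
            Q = latent_block_correlation(block, af)
            evals, evecs = np.linalg.eigh(Q)
            self._cache[key] = evecs * np.sqrt(np.clip(evals, 0.0, None))
        return self._cache[key]


def simulate_genotypes(
    layout: GenomeLayout, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate an ``n_samples × J`` genotype matrix with values {0, 1, 2}."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    thresholds = stats.norm.ppf(layout.variant_af)
    G = np.empty((n_samples, layout.n_variants), dtype=np.int8)
    cache = _LatentCache(layout)
    for t, (sl, _) in enumerate(layout.iter_blocks()):
        L = cache.factor(t)
        m = L.shape[0]
        # two independent haplotypes per individual
        z = rng.standard_normal((2, n_samples, m)) @ L.T
        G[:, sl] = (z < thresholds[sl]).sum(axis=0)
    return G


def standardize_genotypes(genotypes: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """Center by ``2f`` and scale by ``√v_j`` using the true frequencies."""
    f = layout.variant_af
    return (genotypes - 2.0 * f) / np.sqrt(layout.variant_var)


def simulate_phenotypes(
    genotypes: np.ndarray,
    layout: GenomeLayout,
    gamma_std: np.ndarray,
    d_tot: np.ndarray,
    sigma_env_direct: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotypes from the additive model with SEM-propagated direct components."""
    G = np.asarray(genotypes)
    if G.shape[1] != layout.n_variants:
        raise ValueError("genotype matrix width must equal the number of variants")
    K = gamma_std.shape[1]
    gen_direct = standardize_genotypes(G, layout) @ gamma_std
    evals, evecs = np.linalg.eigh(np.asarray(sigma_env_direct))
    Ls = evecs * np.sqrt(np.clip(evals, 0.0, None))
    env_direct = rng.standard_normal((G.shape[0], K)) @ Ls.T
    return (gen_direct + env_direct) @ (np.eye(K) + np.asarray(d_tot))


def build_membership(design: smp.SampleDesign) -> tuple[int, list[np.ndarray]]:
    """Realize a sample design as membership sets over one union cohort.

    Each trait pair with overlap ``N_{k,k'}`` gets a dedicated pool of shared
    samples (no three-way overlap), then each trait is topped up with
    exclusive samples.  Requires ``N_k ≥ Σ_{k'≠k} N_{k,k'}``.  Returns the
    union cohort size and one sorted index array per trait.
    """
    N = design.n_matrix
    K = design.n_traits
    sizes = np.diag(N)
    pair_sum = N.sum(axis=1) - sizes
    if np.any(pair_sum > sizes):
        raise ValueError(
            "sample design needs three-way overlap (some trait's pairwise "
            "overlaps sum past its sample size); not supported"
        )
    members: list[list[int]] = [[] for _ in range(K)]
    cursor = 0
    for k in range(K):
        for kp in range(k + 1, K):
            n_shared = int(N[k, kp])
            if n_shared:
                shared = range(cursor, cursor + n_shared)
                members[k].extend(shared)
                members[kp].extend(shared)
                cursor += n_shared
    for k in range(K):
        n_excl = int(sizes[k]) - len(members[k])
        members[k].extend(range(cursor, cursor + n_excl))
        cursor += n_excl
    return cursor, [np.array(sorted(m), dtype=int) for m in members]


def regression_sumstats(
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    membership: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginal regression slope and SE per variant-trait.

    ``β̂_j = Σ(g−ḡ)(y−ȳ) / Σ(g−ḡ)²`` and
    ``ŝ²_j = [Σ(y−ȳ)²/Σ(g−ḡ)² − β̂²_j] / (N−2)``, each computed over the
    trait's membership samples.  A monomorphic variant within a membership
    set yields NaN with a warning.
    """
    G = np.asarray(genotypes, dtype=float)
    Y = np.asarray(phenotypes, dtype=float)
    K = len(membership)
    J = G.shape[1]
    beta = np.full((J, K), np.nan)
    se = np.full((J, K), np.nan)
    for k, idx in enumerate(membership):
        if idx.size == 0:
            continue
        if idx.size < 3:
            raise ValueError(f"trait {k}: need at least 3 samples for regression")
        g = G[idx]
        y = Y[idx, k]
        n = idx.size
        gc = g - g.mean(axis=0)
        yc = y - y.mean()
        ssx = (gc**2).sum(axis=0)
        ssy = float(yc @ yc)
        mono = ssx == 0
        if mono.any():
            warnings.warn(
                f"trait {k}: {int(mono.sum())} monomorphic variant(s); "
                "estimates reported as missing",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (gc * yc[:, None]).sum(axis=0) / ssx
            s2 = (ssy / ssx - b**2) / (n - 2)
        b[mono] = np.nan
        s2[mono] = np.nan
        beta[:, k] = b
        se[:, k] = np.sqrt(np.maximum(s2, 0.0))
    return beta, se


@dataclass
class IndividualData:
    """Simulated genotypes and phenotypes over a union cohort."""

    genotypes: np.ndarray | None
    phenotypes: np.ndarray | None
    membership: list[np.ndarray]
    n_samples: int
    provenance: dict = field(default_factory=dict)


def resample_inddata(
    sim: Simulation,
    *,
    design: smp.SampleDesign | None = None,
    n_samples: int | None = None,
    genotypes: np.ndarray | None = None,
    phenotypes_only: bool = False,
    genotypes_only: bool = False,
    seed: int | None = None,
    compute_sumstats: bool = False,
):
    """Individual-level data consistent with an existing simulation.

    Three modes mirror the summary-object workflow: generate genotypes and
    phenotypes (default), genotypes only (``genotypes_only=True`` with
    ``n_samples``), or phenotypes only for supplied ``genotypes``
    (``phenotypes_only=True``).  With ``compute_sumstats=True`` the exact
    regression summary statistics are assembled as well (observed traits
    only) and returned as a second value.
    """
    streams = named_streams(np.random.SeedSequence(seed))
    layout = sim.layout
    if genotypes_only:
        if n_samples is None:
            raise ValueError("genotypes_only mode needs n_samples")
        G = simulate_genotypes(layout, n_samples, streams["genotypes"])
        return IndividualData(
            genotypes=G,
            phenotypes=None,
            membership=[],
            n_samples=n_samples,
            provenance={"seed": seed, "mode": "genotypes"},
        )

    if phenotypes_only:
        if genotypes is None:
            raise ValueError("phenotypes_only mode needs genotypes")
        G = np.asarray(genotypes)
        if design is None:
            # no GWAS bookkeeping requested: phenotypes for every sample
            n_union, membership = G.shape[0], []
        else:
            n_union, membership = build_membership(design)
            if G.shape[0] < n_union:
                raise ValueError(
                    f"design needs a union cohort of {n_union} samples but only "
                    f"{G.shape[0]} genotypes were supplied"
                )
    else:
        if design is None:
            design = sim.design
        n_union, membership = build_membership(design)
        G = simulate_genotypes(layout, n_union, streams["genotypes"])
    Y = simulate_phenotypes(
        G,
        layout,
        sim.effects.gamma_std,
        sim.model.d_tot,
        sim.model.sigma_env_direct,
        streams["phenotypes"],
    )
    data = IndividualData(
        genotypes=None if phenotypes_only else G,
        phenotypes=Y,
        membership=membership,
        n_samples=n_union,
        provenance={"seed": seed, "mode": "phenotypes" if phenotypes_only else "both"},
    )
    if not compute_sumstats:
        return data
    if not membership:
        raise ValueError("computing summary statistics requires a sample design")
    obs = design.observed
    beta, se = regression_sumstats(G, Y, [membership[k] for k in obs])
    se_true = smp.true_standard_errors(layout, design.sizes[obs])
    sumstats = smp.assemble_sumstats(
        beta, se_true, se, design, layout, provenance={"seed": seed, "method": "regression"}
    )
    return data, sumstats


def resample_sumstats(
    sim: Simulation,
    design: smp.SampleDesign | None = None,
    *,
    new_layout: GenomeLayout | None = None,
    simulate_se: bool = True,
    seed: int | None = None,
) -> smp.SummaryStats:
    """Fresh summary statistics with the same true (joint) effects.

    Optionally under a new sample design and/or a new LD layout (same number
    of variants): joint effects are reused, marginal effects recomputed under
    the new LD, and a fresh noise draw taken.
    """
    layout = sim.layout if new_layout is None else new_layout
    if layout.n_variants != sim.layout.n_variants:
        raise ValueError("new layout must keep the number of variants unchanged")
    if design is None:
        design = sim.design
    effmat = sim.effects
    if new_layout is not None:
        from dataclasses import replace

        effmat = replace(
            effmat, beta_marg_std=compute_marginal_effects(effmat.beta_joint_std, layout)
        )
    streams = named_streams(np.random.SeedSequence(seed))
    return _draw_sumstats(
        sim.model, layout, design, effmat, streams, simulate_se=simulate_se, seed=seed
    )
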