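"""One-call simulation of a multi-trait GWAS summary-statistic data set."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import effects as eff
from . import sampling as smp
from .ld import GenomeLayout, LDPattern, make_ld_pattern, tile_pattern
from .sem import TraitModel, TraitSEM, build_trait_model

__all__ = ["Simulation", "simulate", "named_streams"]

_STREAM_NAMES = ("allele_freq", "effects", "estimates", "standard_errors", "genotypes", "phenotypes")


def named_streams(seed: int | np.random.SeedSequence) -> dict[str, np.random.Generator]:
    """Deterministic named child RNG streams from one root seed.

    Each stage of the simulation (effect draws, estimate noise, SE draws,
    genotypes, phenotypes) consumes its own stream, so e.g. effect draws are
    reproducible independently of whether SEs are simulated downstream.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAM_NAMES, children)}


@dataclass
class Simulation:
    """Everything produced by one simulation run.

    Holds the solved trait model, the genome layout, the true effect
    matrices (all traits) and the summary statistics (observed traits only),
    plus the sample design and seed for resampling.
    """

    model: TraitModel
    layout: GenomeLayout
    design: smp.SampleDesign
    effects: eff.EffectMatrices
    sumstats: smp.SummaryStats
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return self.layout.n_variants

    @property
    def n_traits(self) -> int:
        return self.model.n_traits


def _resolve_layout(
    J: int,
    ld_pattern: LDPattern | None,
    allele_freq,
    rng: np.random.Generator,
) -> GenomeLayout:
    if ld_pattern is None:
        if allele_freq is None:
            # no LD by default; frequencies drawn once from U(0.05, 0.95)
            af = rng.uniform(0.05, 0.95, size=J)
        else:
            af = np.broadcast_to(np.asarray(allele_freq, dtype=float), (J,)).copy()
        ld_pattern = make_ld_pattern("identity", af)
    return tile_pattern(ld_pattern, J)


def simulate(
    direct_effects,
    h2,
    n,
    J: int,
    pi,
    *,
    ld_pattern: LDPattern | None = None,
    allele_freq=None,
    r_obs=None,
    r_env=None,
    effect_distributions=None,
    snp_info: pd.DataFrame | None = None,
    h2_exact: bool = False,
    simulate_se: bool = True,
    seed: int | None = None,
) -> Simulation:
    """Simulate summary statistics for ``K`` causally related traits.

    Parameters
    ----------
    direct_effects : (K, K) array
        Direct-effects matrix of the trait SEM (must describe a DAG).
    h2 : scalar or (K,) array
        Target heritabilities in [0, 1).
    n : scalar, (K,) or (K, K) array
        GWAS sample sizes; the matrix form carries pairwise sample overlaps
        off the diagonal.  A zero size marks a trait as unobserved.
    J : int
        Number of variants to simulate.
    pi : scalar, (K,) or (J, K) array
        Causal probabilities per variant-trait pair.
    ld_pattern : LDPattern, optional
        Block LD pattern, tiled (possibly fractionally) to ``J`` variants.
        Default: no LD.
    allele_freq : array, optional
        Allele frequencies when no LD pattern is given (a pattern carries
        its own); default U(0.05, 0.95) draws.
    r_obs, r_env : (K, K) array, optional
        Observational trait correlation, or correlation of direct
        environmental components (at most one).
    effect_distributions : callable or list of callables, optional
        Scale-family distribution handle(s); default point-normal.
    snp_info : DataFrame, optional
        Per-pattern-position annotations forwarded to the handles (an "AF"
        column is appended automatically).
    h2_exact : bool
        Rescale direct effects so realized direct variances are exact.
    simulate_se : bool
        Simulate standard-error estimates ŝ; otherwise ``SE`` equals the
        true standard error.
    seed : int
        Root seed; mandatory for reproducible runs (defaults to entropy).

    Returns
    -------
    Simulation
    """
    direct_effects = np.atleast_2d(np.asarray(direct_effects, dtype=float))
    sem = TraitSEM(direct_effects=direct_effects, h2=h2, r_obs=r_obs, r_env=r_env)
    model = build_trait_model(sem)
    K = model.n_traits
    design = smp.build_sample_design(n, K)
    streams = named_streams(np.random.SeedSequence(seed))

    layout = _resolve_layout(J, ld_pattern, allele_freq, streams["allele_freq"])
    effmat = eff.simulate_effects(
        layout,
        model.d_tot,
        model.vg_direct,
        pi,
        streams["effects"],
        distributions=effect_distributions,
        snp_info=snp_info,
        h2_exact=h2_exact,
    )
    sumstats = _draw_sumstats(
        model, layout, design, effmat, streams, simulate_se=simulate_se, seed=seed
    )
    metadata = {
        "seed": seed,
        "realized_vg_direct": effmat.realized_vg_direct.tolist(),
        "realized_h2": effmat.realized_h2.tolist(),
        "trait_correlation": model.trait_correlation.tolist(),
        "sigma_env_direct": model.sigma_env_direct.tolist(),
    }
    return Simulation(
        model=model,
        layout=layout,
        design=design,
        effects=effmat,
        sumstats=sumstats,
        seed=seed,
        metadata=metadata,
    )


def _draw_sumstats(
    model: TraitModel,
    layout: GenomeLayout,
    design: smp.SampleDesign,
    effmat: eff.EffectMatrices,
    streams: dict[str, np.random.Generator],
    simulate_se: bool,
    seed,
) -> smp.SummaryStats:
    """Noise stage shared by :func:`simulate` and summary-stat resampling."""
    obs = design.observed
    if obs.size == 0:
        raise ValueError("at least one trait must have a positive sample size")
    sub = design.restrict(obs)
    rho_obs = model.trait_correlation[np.ix_(obs, obs)]
    C = smp.overlap_correlation(sub, rho_obs)
    beta_hat = smp.sample_effect_estimates(
        effmat.beta_marg_std[:, obs], layout, design, C, streams["estimates"]
    )
    se_true = smp.true_standard_errors(layout, design.sizes[obs])
    if simulate_se:
        # realized phenotype variance: the effect draw's heritability replaces
        # the target's share of the unit variance
        trait_var = 1.0 - model.sem.h2[obs] + effmat.realized_h2[obs]
        se_hat = smp.sample_standard_errors(
            layout,
            design,
            rho_obs,
            effmat.beta_marg_std[:, obs],
            streams["standard_errors"],
            trait_variance=trait_var,
        )
    else:
        se_hat = se_true.copy()
    return smp.assemble_sumstats(
        beta_hat,
        se_true,
        se_hat,
        design,
        layout,
        provenance={"seed": seed, "simulate_se": bool(simulate_se)},
    )
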