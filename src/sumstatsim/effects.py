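"""Causal-variant selection and direct/joint/marginal effect simulation.

Direct variant effects are sparse: variant ``j`` is causal for trait ``k``
with probability ``pi[j, k]``, and causal standardized effects
``γ̃_{j,k} = γ_{j,k} √(2 f_j (1 − f_j))`` are drawn from a scale-family
distribution whose total expected variance over the causal set equals the
trait's direct genetic variance ``VG_dir,k``.  With the default point-normal
family this reproduces the classical ``N(0, VG_dir,k / (π_k J))`` draw.

Direct effects propagate through the trait DAG to joint (causal) effects
``β̃(joint)_j = (I + D_totᵀ) γ̃_j`` and, through the LD matrix, to marginal
effects ``β̃(marg) = R β̃(joint)`` applied per tiled block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ld import GenomeLayout

__all__ = [
    "EffectMatrices",
    "select_causal",
    "point_normal",
    "mixture_normal",
    "fixed_effects",
    "make_effect_distribution",
    "sample_direct_effects",
    "apply_h2_exact",
    "compute_joint_effects",
    "compute_marginal_effects",
    "realized_variances",
    "simulate_effects",
]

# A distribution handle draws ``n`` standardized effects whose expected sum
# of squares equals ``total_variance``; ``variant_info`` carries per-variant
# annotations (always including an "AF" allele-frequency column) for
# annotation-aware handles.
EffectDistribution = Callable[[int, float, pd.DataFrame, np.random.Generator], np.ndarray]


class EmptyCausalSetError(RuntimeError):
    """A trait with positive direct genetic variance drew zero causal variants."""


def _normalize_pi(pi, J: int, K: int) -> np.ndarray:
    arr = np.asarray(pi, dtype=float)
    if arr.ndim == 0:
        arr = np.full((J, K), float(arr))
    elif arr.ndim == 1:
        if arr.shape[0] != K:
            raise ValueError(f"vector pi must have length K={K}")
        arr = np.tile(arr, (J, 1))
    elif arr.shape != (J, K):
        raise ValueError(f"matrix pi must have shape ({J}, {K})")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("causal probabilities must lie in [0, 1]")
    return arr


def select_causal(pi, J: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the J×K boolean causal-indicator matrix.

    Entry ``(j, k)`` is true independently with probability ``pi[j, k]``;
    probabilities of exactly 0 or 1 select variants deterministically.
    """
    probs = _normalize_pi(pi, J, K)
    return rng.random((J, K)) < probs


def point_normal() -> EffectDistribution:
    """Normal effects for causal variants (the default scale family)."""

    def draw(n, total_variance, variant_info, rng):
        if n == 0:
            return np.zeros(0)
        return rng.normal(0.0, np.sqrt(total_variance / n), size=n)

    return draw


def mixture_normal(weights: Sequence[float], variances: Sequence[float]) -> EffectDistribution:
    """Scale mixture of normals ``Σ_m τ_m N(0, σ_m²)``, rescaled to the target.

    Component ``variances`` fix the *relative* scale of the components; the
    draw is rescaled so the expected sum of squares equals the requested
    total variance (per-draw expected square ``total_variance / n``).
    """
    tau = np.asarray(weights, dtype=float)
    sig2 = np.asarray(variances, dtype=float)
    if tau.shape != sig2.shape or tau.ndim != 1:
        raise ValueError("weights and variances must be equal-length vectors")
    if np.any(tau < 0) or not np.isclose(tau.sum(), 1.0):
        raise ValueError("mixture weights must be nonnegative and sum to 1")
    if np.any(sig2 < 0) or tau @ sig2 <= 0:
        raise ValueError("component variances must be >= 0 with positive mixture variance")
    base_var = float(tau @ sig2)

    def draw(n, total_variance, variant_info, rng):
        if n == 0:
            return np.zeros(0)
        comp = rng.choice(tau.shape[0], size=n, p=tau)
        raw = rng.normal(0.0, np.sqrt(sig2[comp]))
        return raw * np.sqrt(total_variance / (n * base_var))

    return draw


def fixed_effects(values: Sequence[float]) -> EffectDistribution:
    """Effects fixed up to a scalar: returns ``c · values`` with exact total variance."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0 or np.allclose(vals, 0.0):
        raise ValueError("fixed effect values must not be all zero")

    def draw(n, total_variance, variant_info, rng):
        if n > vals.size:
            raise ValueError(f"need {n} fixed values but only {vals.size} supplied")
        v = vals[:n]
        ss = float(v @ v)
        if ss == 0:
            raise ValueError("leading fixed values are all zero")
        return v * np.sqrt(total_variance / ss)

    return draw


def make_effect_distribution(kind: str, **kwargs) -> EffectDistribution:
    """Named constructor for the built-in scale families.

    ``kind`` is one of ``"point_normal"``, ``"mixture"`` (kwargs ``weights``,
    ``variances``) or ``"fixed"`` (kwarg ``values``).  Custom callables can
    be passed anywhere a handle is accepted.
    """
    if kind == "point_normal":
        return point_normal()
    if kind == "mixture":
        return mixture_normal(kwargs["weights"], kwargs["variances"])
    if kind == "fixed":
        return fixed_effects(kwargs["values"])
    raise ValueError(f"unknown effect distribution kind {kind!r}")


def _variant_info_frame(layout: GenomeLayout, snp_info: pd.DataFrame | None) -> pd.DataFrame:
    """Per-variant annotation table, recycled with the tiling, plus an AF column."""
    J = layout.n_variants
    if snp_info is None:
        info = pd.DataFrame(index=range(J))
    else:
        if len(snp_info) != layout.pattern.pattern_size:
            raise ValueError(
                "annotation table must have one row per LD-pattern position "
                f"({layout.pattern.pattern_size}), got {len(snp_info)}"
            )
        pattern_pos = _pattern_positions(layout)
        info = snp_info.iloc[pattern_pos].reset_index(drop=True)
    info = info.copy()
    info["AF"] = layout.variant_af
    return info


def _pattern_positions(layout: GenomeLayout) -> np.ndarray:
    """Source pattern position of every variant (annotations recycle with tiling)."""
    sizes = [b.shape[0] for b in layout.pattern.blocks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    parts = [np.arange(size) + offsets[src] for src, size in layout.tiled_blocks]
    return np.concatenate(parts)


def sample_direct_effects(
    indicators: np.ndarray,
    vg_direct,
    distributions,
    layout: GenomeLayout,
    rng: np.random.Generator,
    snp_info: pd.DataFrame | None = None,
    expected_causal: np.ndarray | None = None,
) -> np.ndarray:
    """Draw the J×K matrix of standardized direct effects ``γ̃``.

    For trait ``k`` the handle is asked for the realized number of causal
    draws with a total-variance budget of
    ``vg_direct[k] · n_realized / expected_causal[k]`` so each draw carries
    expected square ``vg_direct[k] / expected_causal[k]`` — the scale the
    point-normal model prescribes.  When ``expected_causal`` is omitted the
    realized count is used (exact total variance in expectation).
    """
    ind = np.asarray(indicators, dtype=bool)
    J, K = ind.shape
    vg = np.asarray(vg_direct, dtype=float)
    if callable(distributions):
        dists = [distributions] * K
    else:
        dists = list(distributions)
        if len(dists) != K:
            raise ValueError("need one distribution handle per trait")
    info = _variant_info_frame(layout, snp_info)
    gamma = np.zeros((J, K))
    for k in range(K):
        causal = np.flatnonzero(ind[:, k])
        if vg[k] == 0:
            continue
        if causal.size == 0:
            raise EmptyCausalSetError(
                f"trait {k} has direct genetic variance {vg[k]:.3g} but drew "
                "no causal variants; retry with a new seed or raise pi"
            )
        expected = causal.size if expected_causal is None else float(expected_causal[k])
        total_var = vg[k] * causal.size / expected
        draws = dists[k](causal.size, total_var, info.iloc[causal], rng)
        draws = np.asarray(draws, dtype=float)
        if draws.shape != (causal.size,):
            raise ValueError("effect distribution returned the wrong number of draws")
        gamma[causal, k] = draws
    return gamma


def apply_h2_exact(gamma_std: np.ndarray, layout: GenomeLayout, vg_direct) -> np.ndarray:
    """Rescale each trait's direct effects so ``γ̃ᵀ R γ̃`` hits ``VG_dir`` exactly.

    The quadratic form is evaluated blockwise over the layout.  A trait with
    target 0 gets an all-zero column; a positive target with an all-zero
    column is an error.
    """
    gamma = np.array(gamma_std, dtype=float, copy=True)
    vg = np.asarray(vg_direct, dtype=float)
    qf = _blockwise_quadratic_form(gamma, layout)
    for k in range(gamma.shape[1]):
        if vg[k] == 0:
            gamma[:, k] = 0.0
            continue
        if qf[k] <= 0:
            raise ValueError(
                f"trait {k}: cannot rescale an all-zero effect column to "
                f"direct variance {vg[k]:.3g}"
            )
        gamma[:, k] *= np.sqrt(vg[k] / qf[k])
    return gamma


def _blockwise_quadratic_form(mat: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """Per-column ``xᵀ R x`` over the block-diagonal layout."""
    out = np.zeros(mat.shape[1])
    for sl, block in layout.iter_blocks():
        sub = mat[sl]
        out += np.einsum("jk,ji,ik->k", sub, block, sub)
    return out


def compute_joint_effects(gamma_std: np.ndarray, d_tot: np.ndarray) -> np.ndarray:
    """Joint (causal) effects ``β̃(joint)_j = (I + D_totᵀ) γ̃_j`` per variant."""
    gamma = np.asarray(gamma_std, dtype=float)
    Dtot = np.asarray(d_tot, dtype=float)
    if gamma.shape[1] != Dtot.shape[0]:
        raise ValueError("gamma_std and d_tot disagree on the number of traits")
    return gamma @ (np.eye(Dtot.shape[0]) + Dtot)


def compute_marginal_effects(beta_joint_std: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """Marginal standardized effects ``R β̃(joint)``, applied per tiled block."""
    beta = np.asarray(beta_joint_std, dtype=float)
    if beta.shape[0] != layout.n_variants:
        raise ValueError("beta_joint_std must have one row per variant")
    out = np.empty_like(beta)
    for sl, block in layout.iter_blocks():
        out[sl] = block @ beta[sl]
    return out


def realized_variances(
    gamma_std: np.ndarray, beta_joint_std: np.ndarray, layout: GenomeLayout
) -> tuple[np.ndarray, np.ndarray]:
    """Realized direct variance ``γ̃ᵀRγ̃`` and total heritability ``β̃ᵀRβ̃``."""
    return (
        _blockwise_quadratic_form(gamma_std, layout),
        _blockwise_quadratic_form(beta_joint_std, layout),
    )


@dataclass
class EffectMatrices:
    """Direct, joint and marginal effects with realized-variance bookkeeping.

    Standardized scale throughout (per SD of genotype); ``*_perallele``
    divides by ``√(2 f (1 − f))``.
    """

    gamma_std: np.ndarray
    beta_joint_std: np.ndarray
    beta_marg_std: np.ndarray
    realized_vg_direct: np.ndarray
    realized_h2: np.ndarray
    causal_indicators: np.ndarray

    def perallele(self, which: str, layout: GenomeLayout) -> np.ndarray:
        mat = {
            "direct": self.gamma_std,
            "joint": self.beta_joint_std,
            "marginal": self.beta_marg_std,
        }[which]
        return mat / np.sqrt(layout.variant_var)[:, None]

    @property
    def n_variants(self) -> int:
        return self.gamma_std.shape[0]

    @property
    def n_traits(self) -> int:
        return self.gamma_std.shape[1]


def simulate_effects(
    layout: GenomeLayout,
    d_tot: np.ndarray,
    vg_direct,
    pi,
    rng: np.random.Generator,
    distributions=None,
    snp_info: pd.DataFrame | None = None,
    h2_exact: bool = False,
) -> EffectMatrices:
    """Full effect-simulation pipeline: select, draw, (rescale), propagate."""
    J = layout.n_variants
    K = np.asarray(vg_direct).shape[0]
    probs = _normalize_pi(pi, J, K)
    indicators = select_causal(probs, J, K, rng)
    if distributions is None:
        distributions = point_normal()
    gamma = sample_direct_effects(
        indicators,
        vg_direct,
        distributions,
        layout,
        rng,
        snp_info=snp_info,
        expected_causal=probs.sum(axis=0),
    )
    if h2_exact:
        gamma = apply_h2_exact(gamma, layout, vg_direct)
    beta_joint = compute_joint_effects(gamma, d_tot)
    beta_marg = compute_marginal_effects(beta_joint, layout)
    vg_real, h2_real = realized_variances(gamma, beta_joint, layout)
    return EffectMatrices(
        gamma_std=gamma,
        beta_joint_std=beta_joint,
        beta_marg_std=beta_marg,
        realized_vg_direct=vg_real,
        realized_h2=h2_real,
        causal_indicators=indicators,
    )
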