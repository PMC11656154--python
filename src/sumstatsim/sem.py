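"""Linear structural equation model (SEM) over a trait DAG.

Traits ``Y_1, ..., Y_K`` are related by a linear SEM ``Y = D_dirᵀ Y + δ``
where ``D_dir[k, k']`` is the *direct* effect of trait ``k`` on trait ``k'``
(per standard deviation of each trait) and ``δ_k = G_dir,k + E_dir,k`` is the
sum of the trait's direct genetic and direct environmental components.
Direct genetic components are mutually independent and independent of the
environment; direct environmental components may be correlated.

Every trait has total variance 1 by convention, so the heritability ``h²_k``
splits into a direct part ``VG_dir,k`` (variance of the trait's own genetic
component) and an indirect part ``VG_ind,k`` mediated by upstream traits:

    VG_ind,k = Σ_l D_tot[l, k]² · VG_dir,l
    h² = (I + D_tot∘²)ᵀ VG_dir          (∘² = elementwise square)

with the total-effects matrix ``D_tot = D_dir (I − D_dir)⁻¹`` summing the
products of direct effects over all directed paths.  Because
``I + D_tot = (I − D_dir)⁻¹``, the trait covariance is

    Cov(Y) = (I + D_tot)ᵀ [diag(VG_dir) + Σ_E] (I + D_tot)

where ``Σ_E`` is the covariance of the direct environmental components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TraitSEM",
    "TraitModel",
    "VarianceDecomposition",
    "validate_dag",
    "total_effects",
    "direct_genetic_variance",
    "indirect_genetic_variance",
    "default_env_covariance",
    "env_covariance_from_env_corr",
    "trait_covariance",
    "solve_env_covariance",
    "build_trait_model",
]

_PSD_TOL = 1e-10


class CycleError(ValueError):
    """The direct-effects matrix does not describe an acyclic graph."""


class InfeasibleModelError(ValueError):
    """The requested heritabilities / correlations are jointly impossible."""


def _as_square(mat, name: str) -> np.ndarray:
    arr = np.asarray(mat, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {arr.shape}")
    return arr


def _check_corr(mat, name: str) -> np.ndarray:
    arr = _as_square(mat, name)
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(arr), 1.0, atol=1e-8):
        raise ValueError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(0.5 * (arr + arr.T)).min() < -1e-8:
        raise ValueError(f"{name} is not positive semi-definite")
    return 0.5 * (arr + arr.T)


def validate_dag(direct_effects) -> list[int]:
    """Check that the direct-effects matrix describes a DAG.

    Returns a topological order of the traits (every directed edge goes
    forward in the order).  The check is done graph-theoretically first
    (clear error message), then numerically: a cyclic model makes
    ``I − D_dir`` singular or puts nonzero entries on the diagonal of the
    total-effects matrix.

    Raises
    ------
    CycleError
        If the graph has a cycle or the diagonal is nonzero.
    """
    D = _as_square(direct_effects, "direct_effects")
    if np.any(np.diag(D) != 0):
        raise CycleError("direct_effects must have an all-zero diagonal (no self loops)")
    g = nx.from_numpy_array(D != 0, create_using=nx.DiGraph)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise CycleError("direct_effects implies a cyclic trait graph") from exc
    # numeric confirmation, catches near-cycles masked by cancellation
    K = D.shape[0]
    try:
        Dtot = D @ np.linalg.inv(np.eye(K) - D)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - topological check fires first
        raise CycleError("I - direct_effects is singular (cyclic model)") from exc
    if np.abs(np.diag(Dtot)).max() > 1e-8:  # pragma: no cover - defensive
        raise CycleError("total-effects matrix has nonzero diagonal (cyclic model)")
    return order


def total_effects(direct_effects) -> np.ndarray:
    """Total effects ``D_tot = D_dir (I − D_dir)⁻¹``.

    Entry ``(k, k')`` is the sum over all directed paths ``k → ... → k'`` of
    the products of direct effects along the path.
    """
    D = _as_square(direct_effects, "direct_effects")
    validate_dag(D)
    K = D.shape[0]
    Dtot = D @ np.linalg.inv(np.eye(K) - D)
    # exact zeros on the diagonal (round-off only; DAG guarantees zero)
    np.fill_diagonal(Dtot, 0.0)
    return Dtot


def direct_genetic_variance(direct_effects, h2) -> np.ndarray:
    """Solve ``(I + D_tot∘²)ᵀ VG_dir = h²`` for the direct genetic variances.

    Raises :class:`InfeasibleModelError` if any solution entry is negative,
    i.e. the indirect genetic variance inherited from upstream traits already
    exceeds the requested heritability.
    """
    D = _as_square(direct_effects, "direct_effects")
    h2 = np.asarray(h2, dtype=float)
    if h2.shape != (D.shape[0],):
        raise ValueError("h2 must be a length-K vector")
    if np.any((h2 < 0) | (h2 >= 1)):
        raise ValueError("heritabilities must lie in [0, 1)")
    Dtot = total_effects(D)
    A = (np.eye(D.shape[0]) + Dtot**2).T
    vg = np.linalg.solve(A, h2)
    if np.any(vg < -1e-12):
        bad = int(np.argmin(vg))
        raise InfeasibleModelError(
            f"trait {bad}: indirect genetic variance exceeds the requested "
            f"heritability (direct variance would be {vg[bad]:.4g})"
        )
    return np.clip(vg, 0.0, None)


def indirect_genetic_variance(d_tot, vg_direct) -> np.ndarray:
    """``VG_ind,k = Σ_l D_tot[l,k]² VG_dir,l`` (trait-mediated genetic variance)."""
    Dtot = np.asarray(d_tot, dtype=float)
    vg = np.asarray(vg_direct, dtype=float)
    return (Dtot**2).T @ vg


def default_env_covariance(direct_effects, h2) -> np.ndarray:
    """Diagonal ``Σ_E`` under independent direct environmental components.

    The direct environmental variances solve ``(I + D_tot∘²)ᵀ v_E = 1 − h²``
    so that every trait has total variance exactly 1.
    """
    D = _as_square(direct_effects, "direct_effects")
    h2 = np.asarray(h2, dtype=float)
    Dtot = total_effects(D)
    A = (np.eye(D.shape[0]) + Dtot**2).T
    ve = np.linalg.solve(A, 1.0 - h2)
    if np.any(ve < -1e-12):
        bad = int(np.argmin(ve))
        raise InfeasibleModelError(
            f"trait {bad}: indirect variance alone exceeds total variance 1 "
            "(no nonnegative direct environmental variance exists)"
        )
    return np.diag(np.clip(ve, 0.0, None))


def env_covariance_from_env_corr(direct_effects, h2, r_env) -> np.ndarray:
    """``Σ_E`` from a target correlation matrix of direct environmental components.

    The environmental SDs are solved trait-by-trait in topological order:
    with ``A = I + D_tot`` (unit diagonal), the environmental variance of
    ``Y_k`` is quadratic in the unknown ``s_k`` once upstream SDs are fixed,
    so each trait contributes one scalar quadratic with a unique positive
    root when the model is feasible.
    """
    D = _as_square(direct_effects, "direct_effects")
    h2 = np.asarray(h2, dtype=float)
    R = _check_corr(r_env, "r_env")
    order = validate_dag(D)
    K = D.shape[0]
    A = np.eye(K) + total_effects(D)
    ve_target = 1.0 - h2  # environmental variance of each trait (unit total variance)
    s = np.zeros(K)
    for k in order:
        w = A[:, k]  # w[k] == 1, w[l] nonzero only for upstream l (already solved)
        others = [l for l in range(K) if l != k and w[l] != 0.0]
        b = sum(w[l] * s[l] * R[l, k] for l in others)
        c = sum(
            w[l] * w[m] * s[l] * s[m] * R[l, m] for l in others for m in others
        )
        disc = b * b - (c - ve_target[k])
        if disc < 0 or (-b + np.sqrt(disc)) < 0:
            raise InfeasibleModelError(
                f"trait {k}: no nonnegative environmental SD satisfies the "
                "requested environmental correlation"
            )
        s[k] = -b + np.sqrt(disc)
    return np.outer(s, s) * R


def trait_covariance(direct_effects, vg_direct, sigma_env_direct) -> np.ndarray:
    """Population trait correlation implied by the SEM.

    ``Cov(Y) = (I + D_tot)ᵀ [diag(VG_dir) + Σ_E] (I + D_tot)``; the inputs
    must imply unit trait variances (the package convention) or a
    ``ValueError`` is raised.
    """
    D = _as_square(direct_effects, "direct_effects")
    vg = np.asarray(vg_direct, dtype=float)
    Sig = _as_square(sigma_env_direct, "sigma_env_direct")
    A = np.eye(D.shape[0]) + total_effects(D)
    inner = np.diag(vg) + 0.5 * (Sig + Sig.T)
    if np.linalg.eigvalsh(inner).min() < -_PSD_TOL:
        raise InfeasibleModelError("diag(vg_direct) + sigma_env_direct is not PSD")
    cov = A.T @ inner @ A
    if np.abs(np.diag(cov) - 1.0).max() > 1e-8:
        raise ValueError(
            "inputs imply trait variances different from 1: "
            f"{np.diag(cov)}"
        )
    rho = 0.5 * (cov + cov.T)
    np.fill_diagonal(rho, 1.0)
    return rho


def solve_env_covariance(direct_effects, vg_direct, r_obs) -> np.ndarray:
    """Invert the SEM propagation: ``Σ_E`` reproducing an observational correlation.

    Using ``I + D_tot = (I − D_dir)⁻¹``,

        Σ_E = (I − D_dir)ᵀ R_obs (I − D_dir) − diag(VG_dir).

    Raises :class:`InfeasibleModelError` when the implied ``Σ_E`` is not a
    valid covariance matrix (eigenvalue below −1e−10), e.g. when the
    requested trait correlation exceeds what the environmental components
    can supply given the genetic model.
    """
    D = _as_square(direct_effects, "direct_effects")
    vg = np.asarray(vg_direct, dtype=float)
    R = _check_corr(r_obs, "r_obs")
    B = np.eye(D.shape[0]) - D
    Sig = B.T @ R @ B - np.diag(vg)
    Sig = 0.5 * (Sig + Sig.T)
    evals, evecs = np.linalg.eigh(Sig)
    if evals.min() < -_PSD_TOL:
        raise InfeasibleModelError(
            "requested observational correlation is infeasible: implied "
            f"environmental covariance has eigenvalue {evals.min():.3g}"
        )
    return (evecs * np.clip(evals, 0.0, None)) @ evecs.T


@dataclass
class TraitSEM:
    """User specification of the trait model.

    Parameters
    ----------
    direct_effects : (K, K) array
        ``D_dir``; entry (k, k') is the direct effect of trait k on k'.
    h2 : (K,) array
        Target heritabilities, each in [0, 1).
    r_obs, r_env : (K, K) array, optional
        At most one of: target observational trait correlation, or target
        correlation of the direct environmental components.  Default:
        independent direct environmental components.
    """

    direct_effects: np.ndarray
    h2: np.ndarray
    r_obs: np.ndarray | None = None
    r_env: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.direct_effects = _as_square(self.direct_effects, "direct_effects")
        self.h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if self.h2.size == 1 and self.n_traits > 1:
            self.h2 = np.full(self.n_traits, float(self.h2[0]))
        if self.h2.shape != (self.n_traits,):
            raise ValueError("h2 must have one entry per trait")
        if self.r_obs is not None and self.r_env is not None:
            raise ValueError("specify at most one of r_obs and r_env")
        validate_dag(self.direct_effects)

    @property
    def n_traits(self) -> int:
        return self.direct_effects.shape[0]


@dataclass
class VarianceDecomposition:
    """Per-trait variance bookkeeping: h² = VG_dir + VG_ind; VE = 1 − h²."""

    vg_direct: np.ndarray
    vg_indirect: np.ndarray
    v_env: np.ndarray
    sigma_env_direct: np.ndarray
    trait_correlation: np.ndarray


@dataclass
class TraitModel:
    """Fully solved trait model: SEM plus derived matrices used downstream."""

    sem: TraitSEM
    d_tot: np.ndarray
    decomposition: VarianceDecomposition = field(repr=False)

    @property
    def n_traits(self) -> int:
        return self.sem.n_traits

    @property
    def vg_direct(self) -> np.ndarray:
        return self.decomposition.vg_direct

    @property
    def sigma_env_direct(self) -> np.ndarray:
        return self.decomposition.sigma_env_direct

    @property
    def trait_correlation(self) -> np.ndarray:
        return self.decomposition.trait_correlation


def build_trait_model(sem: TraitSEM) -> TraitModel:
    """Validate and solve a :class:`TraitSEM` into a :class:`TraitModel`."""
    D = sem.direct_effects
    Dtot = total_effects(D)
    vg = direct_genetic_variance(D, sem.h2)
    if sem.r_obs is not None:
        sigma_env = solve_env_covariance(D, vg, sem.r_obs)
    elif sem.r_env is not None:
        sigma_env = env_covariance_from_env_corr(D, sem.h2, sem.r_env)
    else:
        sigma_env = default_env_covariance(D, sem.h2)
    rho = trait_covariance(D, vg, sigma_env)
    decomp = VarianceDecomposition(
        vg_direct=vg,
        vg_indirect=indirect_genetic_variance(Dtot, vg),
        v_env=1.0 - sem.h2,
        sigma_env_direct=sigma_env,
        trait_correlation=rho,
    )
    return TraitModel(sem=sem, d_tot=Dtot, decomposition=decomp)
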