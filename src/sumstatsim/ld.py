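"""Block-diagonal LD patterns, genome tiling, and LD utilities.

An :class:`LDPattern` is an ordered list of within-block variant correlation
matrices with one allele frequency per pattern position.  A pattern of any
size can be tiled to a genome of ``J`` variants: the block list is repeated
as many (possibly fractional) times as needed, a partially used final block
being replaced by its leading principal submatrix (which stays a valid
correlation matrix).  Variants in different tiled blocks are independent by
construction, so long-range LD cannot be represented.

Built-in synthetic generators cover the two standard test patterns: identity
(no LD) and first-order autoregressive blocks with entries ``rho**|i-j|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LDPattern",
    "GenomeLayout",
    "make_ld_pattern",
    "tile_pattern",
    "extract_ld",
    "ld_prune",
    "ld_proxies",
    "read_ld_pattern",
    "write_ld_pattern",
]

_BLOCK_PSD_TOL = 1e-8


def _validate_block(block: np.ndarray, idx: int) -> np.ndarray:
    b = np.asarray(block, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError(f"LD block {idx} is not square")
    if not np.allclose(b, b.T, atol=1e-8):
        raise ValueError(f"LD block {idx} is not symmetric")
    if not np.allclose(np.diag(b), 1.0, atol=1e-8):
        raise ValueError(f"LD block {idx} does not have unit diagonal")
    b = 0.5 * (b + b.T)
    evals, evecs = np.linalg.eigh(b)
    if evals.min() < -_BLOCK_PSD_TOL:
        raise ValueError(
            f"LD block {idx} is not positive semi-definite "
            f"(min eigenvalue {evals.min():.3g})"
        )
    if evals.min() < 0:
        b = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        d = np.sqrt(np.diag(b))
        b = b / np.outer(d, d)
        np.fill_diagonal(b, 1.0)
    return b


@dataclass
class LDPattern:
    """Ordered LD blocks with aligned allele frequencies.

    ``allele_freq`` has one entry per pattern position (sum of block sizes),
    every frequency strictly inside (0, 1).
    """

    blocks: list[np.ndarray]
    allele_freq: np.ndarray

    def __post_init__(self) -> None:
        self.blocks = [_validate_block(b, i) for i, b in enumerate(self.blocks)]
        self.allele_freq = np.asarray(self.allele_freq, dtype=float).ravel()
        if self.allele_freq.shape[0] != self.pattern_size:
            raise ValueError(
                f"allele_freq has length {self.allele_freq.shape[0]} but the "
                f"pattern has {self.pattern_size} positions"
            )
        if np.any((self.allele_freq <= 0) | (self.allele_freq >= 1)):
            raise ValueError("allele frequencies must be strictly inside (0, 1)")

    @property
    def pattern_size(self) -> int:
        return sum(b.shape[0] for b in self.blocks)


def make_ld_pattern(spec, allele_freq) -> LDPattern:
    """Build an :class:`LDPattern` from a compact specification.

    Parameters
    ----------
    spec
        One of:

        * ``"identity"`` — no LD; one 1×1 block per position of ``allele_freq``;
        * ``("ar1", block_size, rho)`` — a single AR1 block, entries
          ``rho**|i-j|`` with ``rho`` in (−1, 1);
        * a sequence of explicit square correlation matrices.
    allele_freq : array
        One frequency per pattern position.
    """
    af = np.asarray(allele_freq, dtype=float).ravel()
    if isinstance(spec, str):
        if spec != "identity":
            raise ValueError(f"unknown LD pattern spec {spec!r}")
        blocks = [np.ones((1, 1)) for _ in range(af.shape[0])]
    elif isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "ar1":
        _, size, rho = spec
        size = int(size)
        rho = float(rho)
        if not -1.0 < rho < 1.0:
            raise ValueError("ar1 correlation parameter must lie in (-1, 1)")
        idx = np.arange(size)
        blocks = [rho ** np.abs(idx[:, None] - idx[None, :])]
    else:
        blocks = [np.asarray(b, dtype=float) for b in spec]
    return LDPattern(blocks=blocks, allele_freq=af)


@dataclass
class GenomeLayout:
    """Tiling of an LD pattern across ``J`` variants.

    ``tiled_blocks`` lists ``(source_block_index, size)`` pairs in genome
    order; a size smaller than the source block means the leading principal
    submatrix of that block.  ``variant_af`` recycles the pattern's allele
    frequencies with the tiling and ``variant_var = 2 f (1 − f)``.
    """

    pattern: LDPattern
    n_variants: int
    tiled_blocks: list[tuple[int, int]]
    variant_af: np.ndarray

    def __post_init__(self) -> None:
        self.variant_af = np.asarray(self.variant_af, dtype=float)

    @property
    def variant_var(self) -> np.ndarray:
        f = self.variant_af
        return 2.0 * f * (1.0 - f)

    @property
    def block_starts(self) -> np.ndarray:
        sizes = np.array([s for _, s in self.tiled_blocks], dtype=int)
        return np.concatenate([[0], np.cumsum(sizes)])[:-1]

    @property
    def block_of_variant(self) -> np.ndarray:
        """Tiled-block index of each variant."""
        sizes = [s for _, s in self.tiled_blocks]
        return np.repeat(np.arange(len(sizes)), sizes)

    def block_matrix(self, tiled_index: int) -> np.ndarray:
        src, size = self.tiled_blocks[tiled_index]
        return self.pattern.blocks[src][:size, :size]

    def iter_blocks(self) -> Iterable[tuple[slice, np.ndarray]]:
        """Yield ``(variant_slice, correlation_matrix)`` per tiled block."""
        start = 0
        for src, size in self.tiled_blocks:
            yield slice(start, start + size), self.pattern.blocks[src][:size, :size]
            start += size

    def materialize(self) -> np.ndarray:
        """Dense J×J LD matrix (small layouts only; used by tests/oracles)."""
        R = np.zeros((self.n_variants, self.n_variants))
        for sl, block in self.iter_blocks():
            R[sl, sl] = block
        return R

    def snp_ids(self) -> list[str]:
        return [f"snp_{j + 1}" for j in range(self.n_variants)]


def tile_pattern(pattern: LDPattern, n_variants: int) -> GenomeLayout:
    """Repeat an LD pattern (possibly fractionally) to cover ``J`` variants."""
    J = int(n_variants)
    if J < 1:
        raise ValueError("n_variants must be >= 1")
    tiled: list[tuple[int, int]] = []
    af_parts: list[np.ndarray] = []
    block_sizes = [b.shape[0] for b in pattern.blocks]
    af_offsets = np.concatenate([[0], np.cumsum(block_sizes)])[:-1]
    remaining = J
    while remaining > 0:
        for src, size in enumerate(block_sizes):
            take = min(size, remaining)
            tiled.append((src, take))
            off = af_offsets[src]
            af_parts.append(pattern.allele_freq[off : off + take])
            remaining -= take
            if remaining == 0:
                break
    return GenomeLayout(
        pattern=pattern,
        n_variants=J,
        tiled_blocks=tiled,
        variant_af=np.concatenate(af_parts),
    )


def extract_ld(layout: GenomeLayout, indices: Sequence[int]) -> np.ndarray:
    """Dense LD submatrix for a set of variant indices (0-based).

    Entries for variants in different tiled blocks are exactly zero.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size != np.unique(idx).size:
        raise ValueError("indices must be distinct")
    if idx.size and (idx.min() < 0 or idx.max() >= layout.n_variants):
        raise IndexError("variant index out of range")
    block_of = layout.block_of_variant
    starts = layout.block_starts
    out = np.zeros((idx.size, idx.size))
    for a, ja in enumerate(idx):
        ba = block_of[ja]
        Rb = layout.block_matrix(ba)
        for b, jb in enumerate(idx):
            if block_of[jb] == ba:
                out[a, b] = Rb[ja - starts[ba], jb - starts[ba]]
    return out


def ld_prune(
    layout: GenomeLayout,
    pvalues,
    r2_threshold: float = 0.1,
    p_threshold: float | None = None,
) -> list[int]:
    """Greedy LD pruning by ascending p-value.

    Variants are visited from smallest to largest p-value (ties broken by
    lower index); a variant is kept iff its squared correlation with every
    previously kept variant is below ``r2_threshold`` and, when given, its
    p-value is at most ``p_threshold``.  Returns indices in the order kept.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.shape[0] != layout.n_variants:
        raise ValueError("pvalues must have one entry per variant")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    if not np.all(np.isfinite(p)):
        raise ValueError("pvalues must be finite")
    order = np.lexsort((np.arange(p.shape[0]), p))
    block_of = layout.block_of_variant
    starts = layout.block_starts
    kept: list[int] = []
    kept_by_block: dict[int, list[int]] = {}
    for j in order:
        if p_threshold is not None and p[j] > p_threshold:
            continue
        b = int(block_of[j])
        ok = True
        if b in kept_by_block:
            Rb = layout.block_matrix(b)
            off = starts[b]
            for k in kept_by_block[b]:
                if Rb[j - off, k - off] ** 2 >= r2_threshold:
                    ok = False
                    break
        if ok:
            kept.append(int(j))
            kept_by_block.setdefault(b, []).append(int(j))
    return kept


def ld_proxies(
    layout: GenomeLayout, index_variants: Sequence[int], r2_threshold: float
) -> dict[int, list[tuple[int, float]]]:
    """LD proxies: per index variant, all other variants with ``r² ≥ threshold``.

    Proxies necessarily lie in the index variant's tiled block.  Returns a
    mapping ``index -> [(proxy_index, r), ...]`` sorted by proxy index.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    block_of = layout.block_of_variant
    starts = layout.block_starts
    out: dict[int, list[tuple[int, float]]] = {}
    for j in index_variants:
        j = int(j)
        if j < 0 or j >= layout.n_variants:
            raise IndexError("variant index out of range")
        b = int(block_of[j])
        Rb = layout.block_matrix(b)
        off = int(starts[b])
        row = Rb[j - off]
        hits = [
            (off + i, float(r))
            for i, r in enumerate(row)
            if off + i != j and r * r >= r2_threshold
        ]
        out[j] = hits
    return out


def write_ld_pattern(pattern: LDPattern, directory) -> None:
    """Write blocks as whitespace-delimited text plus a frequency file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, block in enumerate(pattern.blocks):
        np.savetxt(d / f"block_{i:04d}.txt", block, fmt="%.17g")
    np.savetxt(d / "allele_freq.txt", pattern.allele_freq, fmt="%.17g")


def read_ld_pattern(directory) -> LDPattern:
    """Read a pattern written by :func:`write_ld_pattern`."""
    d = Path(directory)
    files = sorted(d.glob("block_*.txt"))
    if not files:
        raise FileNotFoundError(f"no block_*.txt files in {d}")
    blocks = [np.atleast_2d(np.loadtxt(f)) for f in files]
    af = np.loadtxt(d / "allele_freq.txt").ravel()
    return LDPattern(blocks=blocks, allele_freq=af)
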