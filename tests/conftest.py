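import numpy as np
import pytest

from sumstatsim.individual import indicator_correlation_from_latent
from sumstatsim.ld import make_ld_pattern, tile_pattern


@pytest.fixture
def three_trait_dag():
    """Direct effects 1→2 (0.8), 1→3 (−0.2), 2→3 (0.1)."""
    return np.array(
        [
            [0.0, 0.8, -0.2],
            [0.0, 0.0, 0.1],
            [0.0, 0.0, 0.0],
        ]
    )


@pytest.fixture
def ar1_layout():
    """AR1(5, 0.9) pattern tiled to 12 variants (fractional repeat)."""
    af = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
    pattern = make_ld_pattern(("ar1", 5, 0.9), af)
    return tile_pattern(pattern, 12)


@pytest.fixture
def feasible_block_layout():
    """One 6-variant LD block achievable by binary genotypes (latent AR1)."""
    rng = np.random.default_rng(2024)
    af = rng.uniform(0.3, 0.7, size=6)
    idx = np.arange(6)
    latent = 0.85 ** np.abs(idx[:, None] - idx[None, :])
    block = indicator_correlation_from_latent(latent, af)
    pattern = make_ld_pattern([block], af)
    return tile_pattern(pattern, 6)
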