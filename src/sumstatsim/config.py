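"""Structured simulation configuration and the orchestrated run.

A configuration is a YAML (or plain dict) document with four blocks::

    trait:
      direct_effects: [[0, 0.8, -0.2], [0, 0, 0.1], [0, 0, 0]]
      h2: [0.3, 0.3, 0.3]
      r_obs: ...          # optional, at most one of r_obs / r_env
    design:
      n: 10000            # scalar | vector | KxK matrix with overlaps
      n_variants: 1000
    ld:
      pattern: identity   # identity | {ar1: {block_size: ..., rho: ...}} | {path: dir}
      allele_freq: ...    # optional vector or scalar
    effects:
      pi: 0.1
      distribution: point_normal   # or {mixture: {weights: [...], variances: [...]}} etc.
      h2_exact: false
      annotation_file: ...         # optional TSV, one row per pattern position
    run:
      seed: 1             # mandatory
      output_dir: out/
      simulate_se: true
      write_effects: true

Unknown keys anywhere are rejected so typos fail loudly, and every
validation error carries the config path of the offending field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import make_effect_distribution
from .io import write_effects_table, write_manifest, write_sumstats
from .ld import LDPattern, make_ld_pattern, read_ld_pattern
from .simulate import Simulation, simulate

__all__ = ["SimConfig", "load_config", "run_simulate"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


_ALLOWED = {
    "trait": {"direct_effects", "h2", "r_obs", "r_env"},
    "design": {"n", "n_variants"},
    "ld": {"pattern", "allele_freq"},
    "effects": {"pi", "distribution", "h2_exact", "annotation_file"},
    "run": {"seed", "output_dir", "simulate_se", "write_effects"},
}


def _check_keys(block: dict, name: str) -> None:
    unknown = set(block) - _ALLOWED[name]
    if unknown:
        raise ConfigError(f"{name}: unknown key(s) {sorted(unknown)}")


@dataclass
class SimConfig:
    """Validated simulation configuration."""

    direct_effects: np.ndarray
    h2: np.ndarray
    n: np.ndarray
    n_variants: int
    seed: int
    r_obs: np.ndarray | None = None
    r_env: np.ndarray | None = None
    ld_pattern: LDPattern | None = None
    allele_freq: np.ndarray | None = None
    pi: float | np.ndarray = 0.1
    distribution: object | None = None
    h2_exact: bool = False
    snp_info: pd.DataFrame | None = None
    output_dir: Path = Path("sumstatsim_output")
    simulate_se: bool = True
    write_effects: bool = True
    raw: dict | None = None

    def digest(self) -> str:
        """Stable hash of the raw configuration document."""
        return hashlib.sha256(
            json.dumps(self.raw or {}, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_ld(ld_block: dict, cfg_af) -> tuple[LDPattern | None, np.ndarray | None]:
    pattern_spec = ld_block.get("pattern", "identity")
    af = None if cfg_af is None else np.asarray(cfg_af, dtype=float)
    if pattern_spec == "identity" or pattern_spec is None:
        return None, af  # identity is the built-in default in simulate()
    if isinstance(pattern_spec, dict):
        if "ar1" in pattern_spec:
            ar1 = pattern_spec["ar1"]
            size = int(ar1["block_size"])
            rho = float(ar1["rho"])
            if af is None:
                raise ConfigError("ld.allele_freq: required for an ar1 pattern")
            if af.ndim == 0 or af.size == 1:
                af = np.full(size, float(np.ravel(af)[0]))
            return make_ld_pattern(("ar1", size, rho), af), None
        if "path" in pattern_spec:
            return read_ld_pattern(pattern_spec["path"]), None
    raise ConfigError(f"ld.pattern: unrecognized spec {pattern_spec!r}")


def _parse_distribution(spec):
    if spec is None or spec == "point_normal":
        return None
    if isinstance(spec, dict):
        (kind, kwargs), = spec.items()
        return make_effect_distribution(kind, **kwargs)
    raise ConfigError(f"effects.distribution: unrecognized spec {spec!r}")


def load_config(source) -> SimConfig:
    """Parse and validate a config from a YAML path, YAML text, or dict."""
    if isinstance(source, dict):
        doc = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(doc) - set(_ALLOWED)
    if unknown:
        raise ConfigError(f"unknown top-level block(s) {sorted(unknown)}")
    for name in ("trait", "design", "run"):
        if name not in doc:
            raise ConfigError(f"{name}: block is required")
    trait = dict(doc["trait"])
    design = dict(doc["design"])
    ld = dict(doc.get("ld", {}))
    effects = dict(doc.get("effects", {}))
    run = dict(doc["run"])
    for name, block in (("trait", trait), ("design", design), ("ld", ld),
                        ("effects", effects), ("run", run)):
        _check_keys(block, name)

    if "direct_effects" not in trait:
        raise ConfigError("trait.direct_effects: required")
    if "h2" not in trait:
        raise ConfigError("trait.h2: required")
    if "n" not in design or "n_variants" not in design:
        raise ConfigError("design.n and design.n_variants: required")
    if "seed" not in run:
        raise ConfigError("run.seed: required (reproducibility is mandatory)")
    if trait.get("r_obs") is not None and trait.get("r_env") is not None:
        raise ConfigError("trait: specify at most one of r_obs and r_env")

    ld_pattern, allele_freq = _parse_ld(ld, ld.get("allele_freq"))
    snp_info = None
    if effects.get("annotation_file"):
        snp_info = pd.read_csv(effects["annotation_file"], sep="\t")

    cfg = SimConfig(
        direct_effects=np.atleast_2d(np.asarray(trait["direct_effects"], dtype=float)),
        h2=np.atleast_1d(np.asarray(trait["h2"], dtype=float)),
        n=np.asarray(design["n"], dtype=float),
        n_variants=int(design["n_variants"]),
        seed=int(run["seed"]),
        r_obs=None if trait.get("r_obs") is None else np.asarray(trait["r_obs"], dtype=float),
        r_env=None if trait.get("r_env") is None else np.asarray(trait["r_env"], dtype=float),
        ld_pattern=ld_pattern,
        allele_freq=allele_freq,
        pi=effects.get("pi", 0.1),
        h2_exact=bool(effects.get("h2_exact", False)),
        snp_info=snp_info,
        output_dir=Path(run.get("output_dir", "sumstatsim_output")),
        simulate_se=bool(run.get("simulate_se", True)),
        write_effects=bool(run.get("write_effects", True)),
        raw=doc,
    )
    cfg.distribution = _parse_distribution(effects.get("distribution"))
    return cfg


def run_config(config: SimConfig) -> Simulation:
    """Run the simulation a config describes (no files written)."""
    return simulate(
        config.direct_effects,
        config.h2,
        config.n,
        config.n_variants,
        config.pi,
        ld_pattern=config.ld_pattern,
        allele_freq=config.allele_freq,
        r_obs=config.r_obs,
        r_env=config.r_env,
        effect_distributions=config.distribution,
        snp_info=config.snp_info,
        h2_exact=config.h2_exact,
        simulate_se=config.simulate_se,
        seed=config.seed,
    )


def run_simulate(config: SimConfig) -> dict:
    """Run a configured simulation and write the output bundle.

    Writes per-trait summary-statistic TSVs, optionally the true-effects
    table, and a JSON run manifest recording realized heritabilities, trait
    correlation, environmental covariance, the config digest and the package
    version.  Returns the manifest dict (with file paths).
    """
    sim = run_config(config)
    out = Path(config.output_dir)
    paths = write_sumstats(sim.sumstats, out)
    manifest = dict(sim.metadata)
    manifest.update(
        {
            "config_digest": config.digest(),
            "package_version": __version__,
            "n_variants": sim.n_variants,
            "n_traits": sim.n_traits,
            "sumstat_files": [str(p) for p in paths],
        }
    )
    if config.write_effects:
        eff_path = write_effects_table(sim, out / "true_effects.tsv")
        manifest["effects_file"] = str(eff_path)
    write_manifest(manifest, out / "manifest.json")
    return manifest
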