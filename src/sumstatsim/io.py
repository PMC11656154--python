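"""Reading and writing the package's tab-separated file dialect.

All floats are written in scientific notation with 17 significant digits
(round-trip exact for doubles), tab-delimited, LF line endings.  Summary
statistics are one table per trait; gzip is applied automatically for paths
ending in ``.gz``.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ld import GenomeLayout
from .sampling import SummaryStats

__all__ = [
    "write_sumstats",
    "read_sumstats",
    "write_effects_table",
    "write_matrix_table",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"
SUMSTAT_COLUMNS = ["SNP", "AF", "BETA", "SE", "SE_TRUE", "Z", "P", "N"]


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", newline="\n")
    return open(path, mode, newline="\n")


def write_sumstats(sumstats: SummaryStats, directory, prefix: str = "sumstats") -> list[Path]:
    """Write one ``<prefix>_<trait>.tsv`` per observed trait; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, frame in sumstats.to_frames().items():
        path = d / f"{prefix}_{label}.tsv"
        with _open_text(path, "w") as fh:
            frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
        paths.append(path)
    return paths


def read_sumstats(path) -> pd.DataFrame:
    """Read one per-trait summary-statistic table, validating the dialect."""
    path = Path(path)
    with _open_text(path, "r") as fh:
        frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    missing = [c for c in SUMSTAT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return frame


def write_effects_table(sim, path) -> Path:
    """True-effects table: per variant, standardized and per-allele effect scales."""
    layout: GenomeLayout = sim.layout
    eff = sim.effects
    data = {"SNP": layout.snp_ids(), "AF": layout.variant_af}
    root_sqrt_v = np.sqrt(layout.variant_var)
    for k in range(eff.n_traits):
        t = f"trait_{k + 1}"
        data[f"GAMMA_STD_{t}"] = eff.gamma_std[:, k]
        data[f"BETA_JOINT_STD_{t}"] = eff.beta_joint_std[:, k]
        data[f"BETA_MARG_STD_{t}"] = eff.beta_marg_std[:, k]
        data[f"GAMMA_PERALLELE_{t}"] = eff.gamma_std[:, k] / root_sqrt_v
        data[f"BETA_JOINT_PERALLELE_{t}"] = eff.beta_joint_std[:, k] / root_sqrt_v
        data[f"BETA_MARG_PERALLELE_{t}"] = eff.beta_marg_std[:, k] / root_sqrt_v
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _open_text(path, "w") as fh:
        pd.DataFrame(data).to_csv(
            fh, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
        )
    return path


def write_matrix_table(matrix, path, columns: list[str], index_ids: list[str] | None = None) -> Path:
    """Generic delimited matrix (genotypes, phenotypes) with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(np.asarray(matrix), columns=columns)
    if index_ids is not None:
        frame.insert(0, "ID", index_ids)
    with _open_text(path, "w") as fh:
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def write_manifest(metadata: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
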