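"""Summaries, Manhattan-style export, and run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "summarize_per_trait",
    "ManhattanExport",
    "export_manhattan",
    "write_manifest",
]


def summarize_per_trait(
    results: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait tallies of tests, significant calls and direction split.

    When a ground-truth table (columns snp_id, trait, is_dase) is supplied —
    available for synthetic runs — empirical power and false-discovery
    proportion columns are added so the run manifest can audit the calls.
    """
    cols = [
        "trait",
        "n_tests",
        "n_significant",
        "n_direction_high",
        "n_direction_low",
        "mean_samples_high",
        "mean_samples_low",
    ]
    if results.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    truth_idx = None
    if truth is not None:
        truth_idx = truth.set_index(["snp_id", "trait"])["is_dase"]
    for trait, block in results.groupby("trait", sort=True):
        sig = block[block["fdr"] <= fdr_alpha]
        row = {
            "trait": trait,
            "n_tests": len(block),
            "n_significant": len(sig),
            "n_direction_high": int((sig["log2fc"] > 0).sum()),
            "n_direction_low": int((sig["log2fc"] < 0).sum()),
            "mean_samples_high": float(block["n_high"].mean()),
            "mean_samples_low": float(block["n_low"].mean()),
        }
        if truth_idx is not None:
            keys = list(zip(block["snp_id"], block["trait"]))
            is_true = truth_idx.reindex(keys).fillna(False).to_numpy(dtype=bool)
            called = (block["fdr"] <= fdr_alpha).to_numpy(dtype=bool)
            n_true = int(is_true.sum())
            row["empirical_power"] = float((called & is_true).sum() / n_true) if n_true else np.nan
            row["empirical_fdp"] = (
                float((called & ~is_true).sum() / called.sum()) if called.sum() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ManhattanExport:
    """Plot-ready table plus bookkeeping for excluded tests."""

    table: pd.DataFrame
    excluded: dict[str, int]
    thresholds: dict[str, float]  # per-trait BH p-value cutoff at fdr_alpha


def export_manhattan(results: pd.DataFrame, fdr_alpha: float = 0.05) -> ManhattanExport:
    """One row per converged test: contig, position, -log10 p_diff, trait, flag.

    Unconverged tests are excluded (and counted); tests with missing
    positions are kept but flagged.  The per-trait threshold is the largest
    p_diff among that trait's significant calls (the BH cutoff drawn as the
    line in a Manhattan plot); traits with no significant call get NaN.
    """
    excluded = {"unconverged": 0}
    block = results
    if "converged" in results.columns:
        conv = results["converged"].astype(bool)
        excluded["unconverged"] = int((~conv).sum())
        block = results[conv]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(block["p_diff"].to_numpy(dtype=float))
    table = pd.DataFrame(
        {
            "snp_id": block["snp_id"].to_numpy(),
            "contig": block.get("contig", pd.Series(np.nan, index=block.index)).to_numpy(),
            "position": block.get("position", pd.Series(np.nan, index=block.index)).to_numpy(),
            "trait": block["trait"].to_numpy(),
            "neglog10_p_diff": neglog,
            "significant": (block["fdr"] <= fdr_alpha).to_numpy(),
        }
    )
    table["missing_position"] = table["position"].isna()
    thresholds = {}
    for trait, tb in block.groupby("trait", sort=True):
        sig = tb[tb["fdr"] <= fdr_alpha]
        thresholds[str(trait)] = float(sig["p_diff"].max()) if len(sig) else float("nan")
    return ManhattanExport(table=table, excluded=excluded, thresholds=thresholds)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    inputs: Mapping[str, str | Path] | None = None,
    params: Mapping[str, object] | None = None,
    seeds: Mapping[str, int] | None = None,
    engine: str = "glm",
    extra: Mapping[str, object] | None = None,
    timestamp: str | None = None,
) -> dict:
    """Write a JSON run manifest tying outputs to inputs, parameters and seeds.

    Input files are recorded with SHA-256 digests; package and library
    versions are captured so a deterministic run can be replayed
    byte-identically.
    """
    import scipy
    import statsmodels

    from . import __version__

    manifest = {
        "package": {"name": "dasekit", "version": __version__},
        "python": sys.version.split()[0],
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "engine": engine,
        "inputs": {
            name: {"file": Path(p).name, "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
        "params": dict(params or {}),
        "seeds": dict(seeds or {}),
    }
    if extra:
        manifest["extra"] = dict(extra)
    if timestamp is not None:
        manifest["timestamp"] = timestamp
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
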