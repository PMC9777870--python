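"""Parsing, filtering and design construction for allelic count tables.

Input is the GATK ASEReadCounter dialect: one row per heterozygous SNP per
sample with 1-based positions and refCount/altCount columns, either as one
file per sample or a single long-format table with a ``sample_id`` column.

A (SNP, trait) pair is testable when, in each contrasting group, at least
``min_animals`` group members are heterozygous at the SNP with at least
``min_depth`` ref+alt reads.  For each testable pair a duplicated-sample
count matrix is built: every included sample contributes two observations,
one per allele, with factors for group, sample nested within group, and
allele nested within group.  Because the sample itself is a factor in the
design, no library-size normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .group_selection import ContrastGroups

__all__ = [
    "AseParseError",
    "DesignMatrix",
    "read_ase_counts",
    "filter_testable",
    "nested_design",
    "build_design",
]

_REQUIRED = ("contig", "position", "refCount", "altCount")


class AseParseError(ValueError):
    """Malformed allelic count input."""


def _validate_counts(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise AseParseError(f"{origin}: missing required column(s) {missing}")
    bad_lines: list[str] = []
    for col in ("position", "refCount", "altCount"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if col == "position":
            bad |= vals < 1
        else:
            bad |= vals < 0
        for idx in df.index[bad]:
            # +2: header line plus 1-based numbering
            bad_lines.append(f"line {idx + 2}: invalid {col} value {df.at[idx, col]!r}")
        df[col] = vals
    if bad_lines:
        raise AseParseError(f"{origin}: " + "; ".join(bad_lines))
    df["position"] = df["position"].astype(np.int64)
    df["refCount"] = df["refCount"].astype(np.int64)
    df["altCount"] = df["altCount"].astype(np.int64)
    return df


def read_ase_counts(
    paths: Iterable[str | Path] | str | Path,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read ASEReadCounter-style TSVs into one long-format count table.

    Parameters
    ----------
    paths
        One path or a list of paths.  A file without a ``sample_id`` column is
        taken to be a single-sample file; its sample id comes from
        ``sample_ids`` (parallel to ``paths``) or, failing that, the file
        stem.  Files that already carry ``sample_id`` may hold many samples.
    sample_ids
        Optional explicit sample ids, one per path.

    Returns
    -------
    DataFrame with columns sample_id, contig, position, variantID (synthesised
    as ``contig:position`` when absent), refAllele, altAllele, refCount,
    altCount.  Positions stay 1-based.

    Raises
    ------
    AseParseError
        On missing columns, malformed values (reported with line numbers),
        negative counts, or duplicated (sample, SNP) rows.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if sample_ids is not None and len(sample_ids) != len(paths):
        raise ValueError("sample_ids must be parallel to paths")

    frames = []
    for i, path in enumerate(paths):
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, sep="\t", dtype=str)
        df = _validate_counts(df, str(path))
        if "sample_id" not in df.columns:
            df.insert(0, "sample_id", sample_ids[i] if sample_ids is not None else path.stem)
        if "variantID" not in df.columns:
            df["variantID"] = df["contig"].astype(str) + ":" + df["position"].astype(str)
        for col in ("refAllele", "altAllele"):
            if col not in df.columns:
                df[col] = "N"
        frames.append(
            df[
                [
                    "sample_id",
                    "contig",
                    "position",
                    "variantID",
                    "refAllele",
                    "altAllele",
                    "refCount",
                    "altCount",
                ]
            ]
        )
    counts = pd.concat(frames, ignore_index=True)
    dup = counts.duplicated(subset=["sample_id", "variantID"], keep=False)
    if dup.any():
        keys = counts.loc[dup, ["sample_id", "variantID"]].drop_duplicates()
        raise AseParseError(
            "duplicate (sample, SNP) rows: "
            + ", ".join(f"({r.sample_id}, {r.variantID})" for r in keys.itertuples())
        )
    return counts


def filter_testable(
    counts: pd.DataFrame,
    groups: ContrastGroups,
    min_depth: int = 10,
    min_animals: int = 3,
) -> dict[str, dict[str, list[str]]]:
    """Apply the testability filters for one trait's contrasting groups.

    A sample qualifies at a SNP iff it belongs to a contrasting group, is
    heterozygous there (i.e. a count record exists), and has
    refCount + altCount >= ``min_depth``.  A SNP is testable iff at least
    ``min_animals`` samples qualify in High **and** in Low.

    Returns
    -------
    Mapping snp_id -> {"high": [sample ids], "low": [sample ids]} for testable
    SNPs only; inclusion lists are sorted for determinism.
    """
    high = set(groups.high)
    low = set(groups.low)
    sub = counts[counts["sample_id"].isin(high | low)]
    sub = sub[sub["refCount"] + sub["altCount"] >= min_depth]

    result: dict[str, dict[str, list[str]]] = {}
    for snp_id, block in sub.groupby("variantID", sort=True):
        samples = set(block["sample_id"])
        h = sorted(samples & high)
        l = sorted(samples & low)
        if len(h) >= min_animals and len(l) >= min_animals:
            result[str(snp_id)] = {"high": h, "low": l}
    return result


@dataclass
class DesignMatrix:
    """Duplicated-sample count matrix for one testable SNP x trait.

    ``X`` columns: intercept, High-group indicator, sample dummies nested in
    group (first sample of each group is the reference), then the two
    allele-within-group terms (alt x Low, alt x High); the alt/ref log-ratio
    within each group is the corresponding allele coefficient.
    """

    snp_id: str
    trait: str
    obs: pd.DataFrame  # sample_id, group, allele, count
    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    idx_alt_high: int
    idx_alt_low: int
    n_high: int
    n_low: int


def nested_design(n_high: int, n_low: int) -> tuple[np.ndarray, int, int]:
    """Design matrix of the duplicated-sample model for given group sizes.

    Row order: High samples then Low, one ref row followed by one alt row per
    sample.  Returns ``(X, idx_alt_high, idx_alt_low)``; the first sample of
    each group is the reference level of the nested sample factor.
    """
    if n_high < 1 or n_low < 1:
        raise ValueError("both groups need at least one sample")
    n = n_high + n_low
    m = 2 * n
    p = n + 2  # intercept + group + (n - 2) samples + 2 allele terms
    idx_alt_low, idx_alt_high = p - 2, p - 1
    X = np.zeros((m, p))
    X[:, 0] = 1.0
    for s in range(n):
        in_high = s < n_high
        r = 2 * s
        if in_high:
            X[r : r + 2, 1] = 1.0
        # sample dummy (skip the first sample of each group)
        within = s if in_high else s - n_high
        if within > 0:
            col = (1 + within) if in_high else (n_high + within)
            X[r : r + 2, col] = 1.0
        X[r + 1, idx_alt_high if in_high else idx_alt_low] = 1.0
    return X, idx_alt_high, idx_alt_low


def build_design(
    snp_id: str,
    counts: pd.DataFrame,
    groups: ContrastGroups,
    include: Mapping[str, Sequence[str]],
) -> DesignMatrix:
    """Build the two-rows-per-sample design for one testable SNP.

    ``include`` is the entry from :func:`filter_testable` (``high``/``low``
    sample lists).  Each included sample must have exactly one count record at
    the SNP; it contributes a ref row and an alt row.
    """
    sub = counts[counts["variantID"] == snp_id].set_index("sample_id")
    rows = []
    for group, members in (("High", include["high"]), ("Low", include["low"])):
        for sample in members:
            if sample not in sub.index:
                raise ValueError(f"sample {sample!r} has no count record at {snp_id!r}")
            rec = sub.loc[sample]
            rows.append((sample, group, "ref", int(rec["refCount"])))
            rows.append((sample, group, "alt", int(rec["altCount"])))
    obs = pd.DataFrame(rows, columns=["sample_id", "group", "allele", "count"])

    n_high = len(include["high"])
    n_low = len(include["low"])
    X, idx_alt_high, idx_alt_low = nested_design(n_high, n_low)
    colnames = (
        ["intercept", "group[High]"]
        + [f"sample[High:{s}]" for s in include["high"][1:]]
        + [f"sample[Low:{s}]" for s in include["low"][1:]]
        + ["alt[Low]", "alt[High]"]
    )

    return DesignMatrix(
        snp_id=snp_id,
        trait=groups.trait,
        obs=obs,
        y=obs["count"].to_numpy(dtype=float),
        X=X,
        colnames=colnames,
        idx_alt_high=idx_alt_high,
        idx_alt_low=idx_alt_low,
        n_high=n_high,
        n_low=n_low,
    )
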